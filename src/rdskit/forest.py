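"""Recruitment-forest construction and validation.

The referral codes imply the full recruitment structure: every non-seed
code's recruiter is the code with the last nonzero digit dropped.  Building
the forest from codes alone makes construction order-independent and lets an
optional explicit edge list be cross-validated rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .codes import MAX_SIBLING, ReferralCode, format_referral_code
from .errors import (
    CouponLimitError,
    DuplicateCodeError,
    MissingParentError,
)
from .records import ParticipantRecord


@dataclass
class RecruitmentForest:
    """The set of referral trees rooted at seeds.

    ``graph`` is a directed forest with recruiter -> recruit edges, node keys
    are pids.  Invariants (checked at construction): each non-seed has exactly
    one recruiter, no recruiter exceeds the five-coupon allowance, and a
    child's wave is its parent's wave plus one.
    """

    nodes: dict[str, ParticipantRecord]
    graph: nx.DiGraph
    roots: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def records(self) -> list[ParticipantRecord]:
        """Records in deterministic (code) order."""
        return [self.nodes[p] for p in sorted(self.nodes, key=lambda p: self.nodes[p].code)]

    def edges(self) -> list[tuple[str, str]]:
        """Recruiter -> recruit pid pairs, in deterministic order."""
        return sorted(self.graph.edges())

    def children(self, pid: str) -> list[str]:
        return sorted(self.graph.successors(pid), key=lambda p: self.nodes[p].code)

    def recruiter_of(self, pid: str) -> str | None:
        preds = list(self.graph.predecessors(pid))
        return preds[0] if preds else None

    @property
    def max_wave(self) -> int:
        return max(r.wave for r in self.nodes.values())

    def wave_of(self, pid: str) -> int:
        return self.nodes[pid].wave

    def records_by_wave(self) -> dict[int, list[ParticipantRecord]]:
        out: dict[int, list[ParticipantRecord]] = {}
        for r in self.records:
            out.setdefault(r.wave, []).append(r)
        return out

    def subset(self, pids: set[str]) -> "RecruitmentForest":
        """Sub-forest on a pid subset.

        Edges with an excluded endpoint are dropped; recruits whose recruiter
        fell outside the subset become roots of their own (pseudo-seed) trees.
        Used for stratified estimation.
        """
        nodes = {p: r for p, r in self.nodes.items() if p in pids}
        g = self.graph.subgraph(pids).copy()
        roots = sorted(p for p in nodes if g.in_degree(p) == 0)
        return RecruitmentForest(nodes=nodes, graph=g, roots=roots)


def build_recruitment_forest(records: list[ParticipantRecord]) -> RecruitmentForest:
    """Assemble the forest implied by the records' referral codes.

    Raises
    ------
    DuplicateCodeError
        Two records share a referral code.
    MissingParentError
        A non-seed's recruiter code is absent; lists every absent code.
    CouponLimitError
        Some recruiter has more than five recruits.
    """
    # Coupon allowance first, counted on the raw records: six recruits of one
    # recruiter necessarily collide in the sibling-digit code space, and the
    # useful diagnosis there is the coupon violation, not the collision.
    raw_children: dict[ReferralCode, int] = {}
    for r in records:
        if not r.is_seed:
            p = r.code.parent()
            raw_children[p] = raw_children.get(p, 0) + 1
    over_raw = {p: c for p, c in raw_children.items() if c > MAX_SIBLING}
    if over_raw:
        worst = max(over_raw, key=over_raw.get)
        raise CouponLimitError(
            f"recruiter {format_referral_code(worst)} has {over_raw[worst]} "
            f"recruits, exceeding the {MAX_SIBLING}-coupon allowance"
        )

    by_code: dict[ReferralCode, ParticipantRecord] = {}
    for r in records:
        if r.code in by_code:
            raise DuplicateCodeError(
                f"referral code {format_referral_code(r.code)} used by both "
                f"{by_code[r.code].pid} and {r.pid}"
            )
        by_code[r.code] = r

    missing = sorted(
        {
            format_referral_code(r.code.parent())
            for r in records
            if not r.is_seed and r.code.parent() not in by_code
        }
    )
    if missing:
        raise MissingParentError(
            f"{len(missing)} recruiter code(s) absent from the data: "
            + ", ".join(missing),
            missing_codes=missing,
        )

    g = nx.DiGraph()
    g.add_nodes_from(r.pid for r in records)
    n_children: dict[str, int] = {}
    for r in records:
        if r.is_seed:
            continue
        parent = by_code[r.code.parent()]
        g.add_edge(parent.pid, r.pid)
        n_children[parent.pid] = n_children.get(parent.pid, 0) + 1
    over = {p: c for p, c in n_children.items() if c > MAX_SIBLING}
    if over:
        worst = max(over, key=over.get)
        raise CouponLimitError(
            f"recruiter {worst} has {over[worst]} recruits, exceeding the "
            f"{MAX_SIBLING}-coupon allowance"
        )

    nodes = {r.pid: r for r in records}
    roots = sorted(
        (r.pid for r in records if r.is_seed), key=lambda p: nodes[p].code
    )
    return RecruitmentForest(nodes=nodes, graph=g, roots=roots)


def cross_validate_edges(forest: RecruitmentForest, edges_path) -> None:
    """Check an explicit edge file (recruiter_pid, recruit_pid) against codes.

    Raises ``MissingParentError`` if the file disagrees with the code-derived
    forest in either direction.
    """
    df = pd.read_csv(edges_path, dtype=str)
    need = {"recruiter_pid", "recruit_pid"}
    if not need <= set(df.columns):
        from .errors import SchemaError

        raise SchemaError(f"edge file {edges_path} must have columns {sorted(need)}")
    file_edges = {(a, b) for a, b in zip(df["recruiter_pid"], df["recruit_pid"])}
    code_edges = set(forest.graph.edges())
    extra = sorted(file_edges - code_edges)
    absent = sorted(code_edges - file_edges)
    if extra or absent:
        raise MissingParentError(
            f"edge file disagrees with referral codes: {len(extra)} edge(s) "
            f"not implied by codes, {len(absent)} code-implied edge(s) missing"
        )


def write_edges(forest: RecruitmentForest, path) -> None:
    pd.DataFrame(forest.edges(), columns=["recruiter_pid", "recruit_pid"]).to_csv(
        path, index=False
    )
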