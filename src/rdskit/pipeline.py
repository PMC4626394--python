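"""End-to-end analysis: composites, stratified estimation, and reporting.

``run_analysis`` composes the whole pipeline — forest validation, composite
traits, crude / equilibrium / RDS-adjusted estimation with dependent-
bootstrap uncertainty, early- vs late-onset stratification with prevalence
ratios and Wald contrasts, and per-trait equilibrium diagnostics — into one
deterministic, reproducible report.

Stratified estimates are computed on the stratum's sub-forest: recruits whose
recruiter fell in the other stratum become pseudo-seeds of their own trees,
so each stratum is analysed as its own chain-referral sample.  Reported
percentages are rounded to one decimal (mirroring how such tables are
printed) and each ratio is recomputed from the two *reported* stratified
percentages, so the table is internally consistent to the displayed digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .equilibrium import (
    EquilibriumTrace,
    cumulative_wave_proportions,
    seed_composition,
    traces_to_frame,
    waves_to_equilibrium,
)
from .errors import (
    DegenerateChainError,
    InsufficientDataError,
    RDSKitError,
    SchemaError,
)
from .estimator import (
    DegreeSummary,
    TransitionMatrix,
    bootstrap_se,
    crude_proportion,
    equilibrium_proportion,
    estimate_transition_matrix,
    harmonic_mean_degrees,
    prevalence_ratio,
    rds_adjusted_proportion,
    wald_test,
)
from .forest import RecruitmentForest, build_recruitment_forest
from .records import ONSET_EARLY, ONSET_LATE, ParticipantRecord, TraitPartition
from .simulate import (
    CLUB_DRUGS,
    HARD_DRUGS,
    SimulationConfig,
    generate_population,
    simulate_rds,
)

logger = logging.getLogger(__name__)

WINDOWS = ("lifetime", "past_year")
COMPOSITES = ("any_illegal", "any_club", "any_hard")
PATTERNS = ("single_drug", "poly_no_hard", "poly_hard")


# ---------------------------------------------------------------------------
# Composite traits
# ---------------------------------------------------------------------------


def derive_composite_traits(
    records: list[ParticipantRecord],
    drugs: list[str] | None = None,
) -> list[ParticipantRecord]:
    """Add drug composites and mutually exclusive use-pattern traits.

    Per recall window: ``any_illegal`` (any of the base drugs), ``any_club``
    (ketamine / ecstasy / marijuana), ``any_hard`` (methamphetamine /
    heroin), and the exhaustive use-pattern indicators over users —
    ``single_drug`` (exactly one), ``poly_no_hard`` (two or more, none hard),
    ``poly_hard`` (two or more, at least one hard).  Non-users are the
    reference mass, so {none} + the three patterns partition the sample.
    """
    if not records:
        return records
    if drugs is None:
        drugs = sorted(
            {
                t.split(":", 1)[0]
                for t in records[0].traits
                if t.split(":", 1)[0] not in COMPOSITES + PATTERNS
            }
        )
    out = []
    for r in records:
        extra: dict[str, int] = {}
        for window in WINDOWS:
            cols = [f"{d}:{window}" for d in drugs]
            missing = [c for c in cols if c not in r.traits]
            if missing:
                raise SchemaError(
                    f"record {r.pid} missing base trait column(s) {missing}"
                )
            vals = {d: r.traits[f"{d}:{window}"] for d in drugs}
            n_used = sum(vals.values())
            any_hard = int(any(vals.get(d, 0) for d in HARD_DRUGS))
            extra[f"any_illegal:{window}"] = int(n_used > 0)
            extra[f"any_club:{window}"] = int(any(vals.get(d, 0) for d in CLUB_DRUGS))
            extra[f"any_hard:{window}"] = any_hard
            extra[f"single_drug:{window}"] = int(n_used == 1)
            extra[f"poly_no_hard:{window}"] = int(n_used >= 2 and not any_hard)
            extra[f"poly_hard:{window}"] = int(n_used >= 2 and any_hard)
        out.append(r.with_traits(extra))
    return out


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------


@dataclass
class AnalysisOptions:
    bootstrap_B: int = 1000
    rng_seed: int | None = None
    tolerance: float = 0.02
    smoothing: bool = False
    zero_row_policy: str = "uniform"
    stratify: bool = True


@dataclass
class AnalysisReport:
    table: pd.DataFrame
    traces: list[EquilibriumTrace]
    transition_matrices: dict[str, TransitionMatrix]
    degree_summaries: dict[str, DegreeSummary]
    metadata: dict
    run_log: list[str] = field(default_factory=list)


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def _trait_block(
    forest: RecruitmentForest,
    records: list[ParticipantRecord],
    trait: str,
    options: AnalysisOptions,
    rng: np.random.Generator,
    log: list[str],
) -> dict:
    """All estimates for one trait on one (sub)sample; NaNs where degenerate."""
    out: dict = {"n_users": sum(r.traits.get(trait, 0) for r in records), "n": len(records)}
    nan = float("nan")
    out.update(
        prop_crude=nan, prop_equilibrium=nan, prop_adjusted=nan,
        se=nan, ci_lo=nan, ci_hi=nan,
    )
    try:
        part = TraitPartition.from_binary_trait(records, trait)
        out["prop_crude"] = crude_proportion(records, part)["user"].proportion
        T = estimate_transition_matrix(
            forest, part, zero_row_policy=options.zero_row_policy,
            smoothing=options.smoothing,
        )
        out["_T"] = T
        out["_part"] = part
        out["prop_equilibrium"] = equilibrium_proportion(T, len(records), trait)[
            "user"
        ].proportion
        degrees = harmonic_mean_degrees(records, part)
        out["_degrees"] = degrees
        out["prop_adjusted"] = rds_adjusted_proportion(
            T, degrees, len(records), trait
        )["user"].proportion
        boot = bootstrap_se(
            forest, part, "rds_adjusted", B=options.bootstrap_B, rng=rng
        )
        out["se"] = boot.se["user"]
        out["ci_lo"], out["ci_hi"] = boot.ci95["user"]
    except (InsufficientDataError, DegenerateChainError) as exc:
        log.append(f"{trait}: {type(exc).__name__}: {exc}")
    return out


def run_analysis(
    source: list[ParticipantRecord] | SimulationConfig,
    options: AnalysisOptions | None = None,
) -> AnalysisReport:
    """Full analysis of a participant list or a simulation config.

    Deterministic given the data and ``options.rng_seed``: simulation, all
    bootstrap streams, and the emitted tables reproduce byte for byte.
    """
    options = options or AnalysisOptions()
    rng = np.random.default_rng(options.rng_seed)
    log: list[str] = []
    metadata: dict = {
        "rdskit_version": __version__,
        "rng_seed": options.rng_seed,
        "bootstrap_B": options.bootstrap_B,
        "tolerance": options.tolerance,
        "smoothing": options.smoothing,
    }
    if isinstance(source, SimulationConfig):
        metadata["config_hash"] = config_hash(source)
        population = generate_population(source, rng)
        records = simulate_rds(population, source, rng)
        log.append(f"simulated {len(records)} participants over {len(source.years)} round(s)")
    else:
        records = list(source)
        log.append(f"loaded {len(records)} participant records")

    records = derive_composite_traits(records)
    forest = build_recruitment_forest(records)
    log.append(
        f"forest: {len(forest)} nodes, {len(forest.edges())} edges, "
        f"{len(forest.roots)} seeds, max wave {forest.max_wave}"
    )

    drugs = sorted(
        {
            t.split(":", 1)[0]
            for t in records[0].traits
            if t.split(":", 1)[0] not in COMPOSITES + PATTERNS
        }
    )
    trait_stems = list(drugs) + [c for c in COMPOSITES + PATTERNS
                                 if f"{c}:lifetime" in records[0].traits]

    early_pids = {r.pid for r in records if r.onset_stratum == ONSET_EARLY}
    late_pids = {r.pid for r in records if r.onset_stratum == ONSET_LATE}
    sub_early = forest.subset(early_pids) if options.stratify and early_pids else None
    sub_late = forest.subset(late_pids) if options.stratify and late_pids else None

    rows = []
    traces: list[EquilibriumTrace] = []
    t_mats: dict[str, TransitionMatrix] = {}
    deg_sums: dict[str, DegreeSummary] = {}
    for stem in trait_stems:
        for window in WINDOWS:
            trait = f"{stem}:{window}"
            if trait not in records[0].traits:
                continue
            overall = _trait_block(forest, records, trait, options, rng, log)
            row = {
                "window": window,
                "trait": stem,
                "n": overall["n"],
                "n_users": overall["n_users"],
                "pct_crude": _pct(overall["prop_crude"]),
                "pct_equilibrium": _pct(overall["prop_equilibrium"]),
                "pct_rds_adjusted": _pct(overall["prop_adjusted"]),
                "ci_lo": _pct(overall["ci_lo"]),
                "ci_hi": _pct(overall["ci_hi"]),
                "prop_rds_adjusted": overall["prop_adjusted"],
                "se": overall["se"],
            }
            if "_T" in overall:
                t_mats[trait] = overall["_T"]
                part = overall["_part"]
                tr = cumulative_wave_proportions(
                    forest, part, "user", tolerance=options.tolerance
                )
                traces.append(tr)
                row["converged_at_wave"] = tr.converged_at
                try:
                    row["waves_to_equilibrium"] = waves_to_equilibrium(
                        overall["_T"],
                        seed_composition(forest, part),
                        tolerance=options.tolerance,
                    )
                except (DegenerateChainError, RDSKitError) as exc:
                    log.append(f"{trait}: waves_to_equilibrium: {exc}")
                    row["waves_to_equilibrium"] = None
            if "_degrees" in overall:
                deg_sums[trait] = overall["_degrees"]

            if sub_early is not None and sub_late is not None:
                e = _trait_block(sub_early, sub_early.records, trait, options, rng, log)
                l = _trait_block(sub_late, sub_late.records, trait, options, rng, log)
                row.update(
                    n_early=e["n"], n_users_early=e["n_users"],
                    pct_early=_pct(e["prop_adjusted"]),
                    ci_lo_early=_pct(e["ci_lo"]), ci_hi_early=_pct(e["ci_hi"]),
                    n_late=l["n"], n_users_late=l["n_users"],
                    pct_late=_pct(l["prop_adjusted"]),
                    ci_lo_late=_pct(l["ci_lo"]), ci_hi_late=_pct(l["ci_hi"]),
                )
                pe, pl = row["pct_early"], row["pct_late"]
                if np.isfinite(pe) and np.isfinite(pl) and pl > 0:
                    row["ratio"] = prevalence_ratio(pe, pl)
                else:
                    row["ratio"] = float("nan")
                if (
                    np.isfinite(e["se"]) and e["se"] > 0
                    and np.isfinite(l["se"]) and l["se"] > 0
                ):
                    w = wald_test(e["prop_adjusted"], e["se"], l["prop_adjusted"], l["se"])
                    row["wald_z"] = w.z
                    row["p_value"] = w.p_value
                else:
                    row["wald_z"] = float("nan")
                    row["p_value"] = float("nan")
            rows.append(row)

    table = pd.DataFrame(rows)
    return AnalysisReport(
        table=table,
        traces=traces,
        transition_matrices=t_mats,
        degree_summaries=deg_sums,
        metadata=metadata,
        run_log=log,
    )


def _pct(p: float, decimals: int = 1) -> float:
    """Proportion -> percentage at printed precision (half away from zero)."""
    if not np.isfinite(p):
        return float("nan")
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(repr(float(p))) * 100).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Report persistence
# ---------------------------------------------------------------------------


def write_report(report: AnalysisReport, out_dir) -> None:
    """Persist the report and every intermediate needed to recompute it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for window in WINDOWS:
        sub = report.table[report.table["window"] == window]
        if len(sub):
            sub.to_csv(out / f"table_{window}.csv", index=False, float_format="%.10g")
    if report.traces:
        traces_to_frame(report.traces).to_csv(
            out / "equilibrium_traces.csv", index=False, float_format="%.10g"
        )
    tm_rows = []
    for trait, T in report.transition_matrices.items():
        for i, a in enumerate(T.groups):
            for j, b in enumerate(T.groups):
                tm_rows.append(
                    {"trait": trait, "from_group": a, "to_group": b,
                     "count": T.counts[i, j], "prob": T.S[i, j]}
                )
    if tm_rows:
        pd.DataFrame(tm_rows).to_csv(
            out / "transition_matrices.csv", index=False, float_format="%.10g"
        )
    deg_rows = []
    for trait, ds in report.degree_summaries.items():
        for g in ds.groups:
            deg_rows.append(
                {"trait": trait, "group": g, "harmonic_mean_degree": ds.harmonic_mean[g],
                 "n": ds.n[g], "n_excluded": ds.n_excluded[g]}
            )
    if deg_rows:
        pd.DataFrame(deg_rows).to_csv(
            out / "degree_summaries.csv", index=False, float_format="%.10g"
        )
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(report.run_log) + "\n")
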