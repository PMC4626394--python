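"""Referral-code parsing and formatting.

Chain-referral studies track who recruited whom with a positional code: a
four-character seed label (a letter plus three digits, e.g. ``F001``) followed
by a dash and one digit per recruitment wave.  A seed is all zeros
(``F001-0000000000``); each recruit extends its recruiter's code by writing a
nonzero digit in the first free position, so the number of leading nonzero
digits is the recruit's wave.  We give the digit itself a meaning: it is the
recruit's 1-based sibling index (1-5, one per coupon) among that recruiter's
recruits, which keeps codes unique and makes the whole recruitment path
recoverable from the code alone.

The default code carries 10 path digits (waves 0-10).  Deeper simulated chains
use the same dialect with a wider digit field; width is preserved through
parse/format round trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import CodeFormatError, CodeStructureError

#: Default number of path-digit positions (one per wave).
DEFAULT_WIDTH = 10

#: Coupon allowance: the largest legal sibling index.
MAX_SIBLING = 5

_LABEL_RE = re.compile(r"^[A-Za-z][0-9]{3}$")


@dataclass(frozen=True, order=True)
class ReferralCode:
    """A parsed referral code.

    Parameters
    ----------
    seed_label:
        Four characters, letter + three digits (``F001``).
    path_digits:
        One digit in ``0..5`` per wave position; all digits after the first
        zero must be zero (prefix property).
    """

    seed_label: str
    path_digits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not _LABEL_RE.match(self.seed_label):
            raise CodeFormatError(
                f"seed label {self.seed_label!r} must be a letter followed by "
                "three digits",
                position=0,
            )
        if len(self.path_digits) < 1:
            raise CodeFormatError("path digits must not be empty")
        seen_zero = False
        for i, d in enumerate(self.path_digits):
            if not 0 <= d <= MAX_SIBLING:
                raise CodeFormatError(
                    f"path digit {d} at position {i} outside 0..{MAX_SIBLING}",
                    position=len(self.seed_label) + 1 + i,
                )
            if d == 0:
                seen_zero = True
            elif seen_zero:
                raise CodeStructureError(
                    f"nonzero digit at position {i} follows a zero in "
                    f"{self.seed_label}-{''.join(map(str, self.path_digits))}: "
                    "path digits must form a prefix"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def wave(self) -> int:
        """Recruitment depth: number of leading nonzero path digits (seed = 0)."""
        w = 0
        for d in self.path_digits:
            if d == 0:
                break
            w += 1
        return w

    @property
    def width(self) -> int:
        return len(self.path_digits)

    @property
    def is_seed(self) -> bool:
        return self.wave == 0

    # -- relationships ------------------------------------------------------

    def parent(self) -> "ReferralCode":
        """The recruiter's code: drop the last nonzero digit.

        Raises
        ------
        CodeStructureError
            If the code is a seed (seeds have no recruiter).
        """
        if self.is_seed:
            raise CodeStructureError(f"seed code {self} has no parent")
        w = self.wave
        digits = list(self.path_digits)
        digits[w - 1] = 0
        return ReferralCode(self.seed_label, tuple(digits))

    def child(self, sibling_index: int) -> "ReferralCode":
        """The code of this participant's ``sibling_index``-th recruit (1-based)."""
        if not 1 <= sibling_index <= MAX_SIBLING:
            raise CodeStructureError(
                f"sibling index {sibling_index} outside 1..{MAX_SIBLING}"
            )
        w = self.wave
        if w >= self.width:
            raise CodeStructureError(
                f"code {self} is at maximum representable wave {self.width}"
            )
        digits = list(self.path_digits)
        digits[w] = sibling_index
        return ReferralCode(self.seed_label, tuple(digits))

    def __str__(self) -> str:
        return format_referral_code(self)


def parse_referral_code(text: str) -> ReferralCode:
    """Parse ``'F001-1100000000'`` into a :class:`ReferralCode`.

    The label must be four characters (letter + three digits), followed by a
    dash and at least :data:`DEFAULT_WIDTH` path digits in ``0..5`` satisfying
    the prefix property.

    Raises
    ------
    CodeFormatError
        Wrong length, charset, or missing dash; names the offending position.
    CodeStructureError
        A nonzero digit appears after a zero.
    """
    if not isinstance(text, str):
        raise CodeFormatError(f"referral code must be a string, got {type(text)!r}")
    if len(text) < 5 or text[4] != "-":
        pos = min(4, len(text))
        raise CodeFormatError(
            f"referral code {text!r} must be '<label>-<digits>' with a dash at "
            "position 4",
            position=pos,
        )
    label, digit_text = text[:4], text[5:]
    if not _LABEL_RE.match(label):
        raise CodeFormatError(
            f"seed label {label!r} in {text!r} must be a letter followed by three digits",
            position=0,
        )
    if len(digit_text) < DEFAULT_WIDTH:
        raise CodeFormatError(
            f"referral code {text!r} has {len(digit_text)} path digits, "
            f"expected at least {DEFAULT_WIDTH}",
            position=len(text),
        )
    digits = []
    for i, ch in enumerate(digit_text):
        if not ch.isdigit() or int(ch) > MAX_SIBLING:
            raise CodeFormatError(
                f"character {ch!r} at position {5 + i} of {text!r} is not a "
                f"digit in 0..{MAX_SIBLING}",
                position=5 + i,
            )
        digits.append(int(ch))
    return ReferralCode(label, tuple(digits))


def format_referral_code(code: ReferralCode) -> str:
    """Inverse of :func:`parse_referral_code`: ``F001-1100000000``."""
    return f"{code.seed_label}-{''.join(str(d) for d in code.path_digits)}"


def seed_code(seed_label: str, width: int = DEFAULT_WIDTH) -> ReferralCode:
    """The all-zero code of a seed with the given label."""
    return ReferralCode(seed_label, (0,) * width)
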