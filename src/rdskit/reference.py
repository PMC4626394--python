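"""Published reference values from the motivating Taipei RDS survey.

The original field data (regular tobacco-and-alcohol users recruited by
chain referral in metropolitan Taipei, 2007-2010) are confidential, but the
published report prints the design arithmetic and the RDS-adjusted
stratified prevalence tables.  Those printed values are inputs here: the
design constants parameterise the default simulation scenario, and the
stratified estimates let the ratio/contrast machinery be checked against
every printed ratio cell.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Participants recruited per yearly round; the pooled sample size is 1115.
YEARLY_SAMPLE_SIZES: dict[int, int] = {2007: 144, 2008: 328, 2009: 350, 2010: 293}

#: Seeds by recruitment setting (35 community venues, 12 hospital
#: drug-rehabilitation programs), 47 in total.
SEED_COUNTS: dict[str, int] = {"community": 35, "hospital": 12}

#: Lifetime any-illegal-drug users observed in the pooled sample.
LIFETIME_ANY_DRUG_USERS: int = 277

#: Stratum sizes by onset age of tobacco smoking (<18 vs >=18 years).
STRATUM_SIZES: dict[str, int] = {"early": 647, "late": 468}

#: Waves of recruitment actually carried out (beyond the seeds).
FIELD_WAVES: int = 8


def load_stratified_estimates() -> pd.DataFrame:
    """The published RDS-adjusted stratified prevalence tables.

    One row per trait x recall window with the weighted percentage, its 95%
    CI and count for the total sample and for each smoking-onset stratum,
    the printed early/late prevalence ratio, and the printed Wald P-value.
    """
    with resources.files("rdskit.data").joinpath(
        "stratified_prevalence_published.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
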