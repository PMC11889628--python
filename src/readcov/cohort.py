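"""Sample assembly: QC filtering, reading-group classification, exclusions,
and two-sample t-tests from printed summary statistics.

Subjects are carried as a pandas DataFrame ("subject table") with one row
per participant. The canonical columns are::

    id, cohort, group, age, sex, handedness, iq_percentile,
    reading_fluency_percentile, tiv, quality_rating, comorbidity, map_ref

``comorbidity`` holds a semicolon-separated set of diagnosis flags (empty
string for none), which keeps the table round-trippable through CSV.

Group classification follows the two-cutoff percentile rule used for
normed reading-fluency scores: at or below the 16th percentile is a poor
reader, at or above the 25th percentile a typical reader, and the band in
between is excluded from group analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

POOR_CUTOFF = 16.0  # reading-fluency percentile <= 16 -> poor reader
TYPICAL_CUTOFF = 25.0  # percentile >= 25 -> typical reader

GROUP_TYPICAL = "typical"
GROUP_POOR = "poor"
GROUP_EXCLUDED = "excluded"

#: diagnosis flags the exclusion machinery understands
KNOWN_COMORBIDITY_FLAGS = frozenset({"ADHD", "dyscalculia"})

SUBJECT_COLUMNS = [
    "id", "cohort", "group", "age", "sex", "handedness", "iq_percentile",
    "reading_fluency_percentile", "tiv", "quality_rating", "comorbidity",
    "map_ref",
]


def classify_reading_group(fluency: float) -> str:
    """Classify one reading-fluency percentile into typical/poor/excluded."""
    if fluency is None or (isinstance(fluency, float) and math.isnan(fluency)):
        raise ValidationError("reading fluency percentile is missing")
    if not 0.0 <= fluency <= 100.0:
        raise ValidationError(
            f"reading fluency percentile {fluency} outside [0, 100]"
        )
    if fluency <= POOR_CUTOFF:
        return GROUP_POOR
    if fluency >= TYPICAL_CUTOFF:
        return GROUP_TYPICAL
    return GROUP_EXCLUDED


def classify_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the ``group`` column set from reading fluency."""
    out = subjects.copy()
    out["group"] = [
        classify_reading_group(f) for f in out["reading_fluency_percentile"]
    ]
    return out


def qc_filter(subjects: pd.DataFrame, threshold: float = 75.0) -> pd.DataFrame:
    """Drop subjects whose MRI quality rating falls below ``threshold`` percent.

    The boundary is retained: a rating exactly at the threshold passes
    ("below" is read strictly). Excluded ids are logged.
    """
    ratings = subjects["quality_rating"]
    if ratings.isna().any():
        raise ValidationError("quality_rating missing for some subjects")
    keep = ratings >= threshold
    dropped = subjects.loc[~keep, "id"].tolist()
    if dropped:
        logger.info("QC filter (< %.6g%%) excluded %d subjects: %s",
                    threshold, len(dropped), ", ".join(map(str, dropped)))
    out = subjects.loc[keep].copy()
    if out.empty:
        warnings.warn("QC filter removed every subject", stacklevel=2)
    return out


def parse_flags(cell: object) -> frozenset[str]:
    """Parse a semicolon-separated comorbidity cell into a set of flags."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(p.strip() for p in text.split(";") if p.strip())


def exclude_comorbid(
    subjects: pd.DataFrame, flags: Iterable[str]
) -> pd.DataFrame:
    """Remove subjects carrying any of the given diagnosis flags."""
    flagset = set(flags)
    unknown = flagset - KNOWN_COMORBIDITY_FLAGS
    if unknown:
        raise ValidationError(
            f"unknown comorbidity flag(s): {sorted(unknown)}; "
            f"known flags: {sorted(KNOWN_COMORBIDITY_FLAGS)}"
        )
    if not flagset:
        return subjects.copy()
    carried = subjects["comorbidity"].map(parse_flags)
    keep = [not (c & flagset) for c in carried]
    out = subjects.loc[keep].copy()
    dropped = subjects.loc[[not k for k in keep], "id"].tolist()
    if dropped:
        logger.info("comorbidity exclusion (%s) removed %d subjects",
                    sorted(flagset), len(dropped))
    if out.empty:
        warnings.warn("comorbidity exclusion removed every subject",
                      stacklevel=2)
    return out


def summary_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Default is the pooled-variance Student test (df = n1 + n2 - 2), which
    matches the degrees of freedom conventionally printed alongside group
    demographic comparisons; ``welch=True`` uses the Welch-Satterthwaite
    approximation instead.

    Returns ``(t, df, p_two_sided)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both groups have zero variance")
    v1, v2 = sd1**2, sd2**2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = (mean1 - mean2) / math.sqrt(se2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            raise DegenerateInputError("pooled variance is zero")
        t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject table from CSV, with empty cells as missing values."""
    df = pd.read_csv(path, dtype={"id": str, "comorbidity": str})
    missing = {"id", "reading_fluency_percentile", "tiv", "quality_rating"} - set(
        df.columns
    )
    if missing:
        raise ValidationError(f"subject CSV lacks required columns: {sorted(missing)}")
    df["comorbidity"] = df.get("comorbidity", "").fillna("")
    return df


def write_subject_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False)
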