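"""Published study inputs carried as package constants.

``SAMPLE_CHARACTERISTICS`` is the printed characteristics table of the 14
tissue samples used for retrospective ¹⁴C dating (eight pilocytic
astrocytomas, two normal cerebella, four glioblastomas): per-case birth
year, diagnosis, age at surgery, brain region, tentorial compartment and
pathology-assessed purity.  The per-sample measured Δ¹⁴C values were
published only in supplementary material and are not carried here; the
simulator stands in for them.

``METHYLATION_COHORT_COUNTS`` is the methylation-cohort accounting: 156 PA
and 72 control brain samples from GEO accession GSE109381, 19 control
tissues from the Allen Brain Atlas, and 10 newly profiled adult PAs.
"""

from __future__ import annotations

import math

import pandas as pd

from .dating import SampleRecord, midyear

__all__ = [
    "SAMPLE_CHARACTERISTICS",
    "METHYLATION_COHORT_COUNTS",
    "sample_characteristics_frame",
    "pa_purity_percent",
    "mean_pa_purity_percent",
    "methylation_cohort_size",
    "dating_records",
]

# case, birth_year, diagnosis, age_at_surgery (years; None = autopsy/unknown),
# brain_region, compartment, purity_percent (None = not assessed; case 12 was
# reported as a ">85%" bound and is carried as 85)
SAMPLE_CHARACTERISTICS: tuple[tuple, ...] = (
    (1, 1988, "pediatric PA", 9, "cerebellum", "infratentorial", 90),
    (2, 1993, "pediatric PA", 2, "3rd ventricle", "supratentorial", 80),
    (3, 1983, "pediatric PA", 10, "cerebellum", "infratentorial", 95),
    (4, 1968, "normal cerebellum", None, "cerebellum", "infratentorial", 95),
    (5, 1950, "glioblastoma", 59, None, None, None),
    (6, 1970, "adult PA", 25, "cerebellum", "infratentorial", 90),
    (7, 1970, "adult PA", 26, "cerebellum", "infratentorial", 70),
    (8, 1979, "adult PA", 26, "diencephalic region", "supratentorial", 100),
    (9, 1972, "adult PA", 40, "4th ventricle", "infratentorial", 80),
    (10, 1959, "adult PA", 33, "pineal region", "supratentorial", 80),
    (11, 1974, "normal cerebellum", 35, "cerebellum", "infratentorial", 95),
    (12, 1970, "glioblastoma", 22, "hemispheres", "supratentorial", 85),
    (13, 1970, "glioblastoma", 22, "hemispheres", "supratentorial", 90),
    (14, 1988, "glioblastoma", 6, "hemispheres", "supratentorial", 90),
)

METHYLATION_COHORT_COUNTS: dict[str, int] = {
    "GSE109381 PA": 156,
    "GSE109381 control brain": 72,
    "Allen Brain Atlas control": 19,
    "newly profiled adult PA": 10,
}

_COLUMNS = (
    "case",
    "birth_year",
    "diagnosis",
    "age_at_surgery",
    "brain_region",
    "compartment",
    "purity_percent",
)


def sample_characteristics_frame() -> pd.DataFrame:
    """The dated-sample characteristics table as a DataFrame."""
    return pd.DataFrame(SAMPLE_CHARACTERISTICS, columns=_COLUMNS).set_index("case")


def pa_purity_percent() -> list[int]:
    """Pathology-assessed tumor purity of the eight PA cases, in percent."""
    return [
        row[6]
        for row in SAMPLE_CHARACTERISTICS
        if row[2] in ("pediatric PA", "adult PA")
    ]


def mean_pa_purity_percent(floor: bool = True) -> float:
    """Mean tumor purity over the PA cases (floored to integer percent by
    default, matching how the cohort-level figure is usually quoted)."""
    purities = pa_purity_percent()
    mean = sum(purities) / len(purities)
    return float(math.floor(mean)) if floor else mean


def methylation_cohort_size() -> int:
    """Total methylation-cohort size across all four sources."""
    return sum(METHYLATION_COHORT_COUNTS.values())


def dating_records(purity_margin: float = 0.05) -> list[SampleRecord]:
    """The characteristics table as dating-ready :class:`SampleRecord` rows.

    Year-only dates map to mid-year; cases without an age at surgery or a
    purity assessment are skipped (they cannot be dated without those
    fields).
    """
    out: list[SampleRecord] = []
    for case, birth, diagnosis, age, _region, compartment, purity in SAMPLE_CHARACTERISTICS:
        if age is None or purity is None:
            continue
        out.append(
            SampleRecord(
                sample_id=f"case{case:02d}",
                birth_year=midyear(birth),
                collection_year=midyear(birth + age),
                purity=purity / 100.0,
                purity_margin=purity_margin,
                tissue_class="control" if diagnosis == "normal cerebellum" else "tumor",
                location=compartment or "",
            )
        )
    return out
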