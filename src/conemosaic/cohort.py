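"""Cohort-level morphometry statistics.

Pools per-cone spot diameters over the four imaged regions of an eye,
summarizes size distributions (histograms, the ≥6.0 μm enlarged-spot
percentage), and runs the group comparisons used in cone-morphometry
studies: independent-sample t tests (Welch by default), Pearson χ² on
2×2 frequency tables, and one-way ANOVA with Tukey–Kramer-adjusted
pairwise comparisons.  All p-values are two-sided.

A small reference cohort table of ten RP cases (per-case metadata and
enlarged-spot percentages) ships with the package for examples and
validation; load it with :func:`load_rp_cohort`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sizing import ENLARGED_THRESHOLD_UM, SpotMeasurement

#: an eye should contribute at least this many unflagged spots
MIN_SPOTS_PER_EYE = 500

REGIONS = ("superior", "inferior", "temporal", "nasal")
EZ_CATEGORIES = ("Normal", "Abnormal", "Disappeared", "NA")


@dataclass
class EyeRecord:
    """Per-eye measurements pooled across regions, with group labels."""

    subject_id: str
    group: str  # "control" | "RP"
    region_measurements: dict[str, list[SpotMeasurement]]
    ez_status: str = "NA"
    eccentricity_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in ("control", "RP"):
            raise ValueError("group must be 'control' or 'RP'")
        if self.ez_status not in EZ_CATEGORIES:
            raise ValueError(f"ez_status must be one of {EZ_CATEGORIES}")
        if not self.region_measurements:
            raise ValueError("at least one region required")


@dataclass
class CohortRow:
    """One row of a cohort characteristics table."""

    case_id: str
    age: float
    sex: str
    inheritance: str
    axial_length_mm: float
    va_logmar: float
    md_db: float
    fs_db: float
    ez_status: str
    enlarged_pct: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.enlarged_pct) or 0.0 <= self.enlarged_pct <= 100.0):
            raise ValueError("enlarged_pct must be in [0, 100]")


@dataclass
class TestResult:
    """A two-sided hypothesis-test result with group summaries."""

    method: str
    statistic: float
    df: float
    p_two_sided: float
    group_summaries: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_two_sided) or 0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p must be in [0, 1]")


def pool_eye(record: EyeRecord) -> np.ndarray:
    """Concatenate unflagged spot diameters (μm) across an eye's regions.

    Warns when the pooled count falls below the per-eye quality minimum
    (500 spots) or when every measurement is flagged.
    """
    diameters = [
        m.diameter_um
        for region in record.region_measurements.values()
        for m in region
        if m.ok
    ]
    if not diameters:
        warnings.warn(
            f"eye {record.subject_id}: all measurements flagged; empty pool",
            stacklevel=2,
        )
    elif len(diameters) < MIN_SPOTS_PER_EYE:
        warnings.warn(
            f"eye {record.subject_id}: only {len(diameters)} unflagged spots "
            f"(expected > {MIN_SPOTS_PER_EYE})",
            stacklevel=2,
        )
    return np.asarray(diameters)


def size_histogram(
    diameters: np.ndarray,
    bin_width_um: float = 0.5,
    range_um: tuple[float, float] = (2.0, 9.0),
) -> pd.DataFrame:
    """Spot-diameter histogram as per-bin percentages.

    Bins of ``bin_width_um`` cover ``range_um``; values outside the range
    are counted in the open end bins, so percentages always sum to 100.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("size_histogram requires at least one diameter")
    lo, hi = range_um
    edges = np.arange(lo, hi + bin_width_um / 2, bin_width_um)
    clipped = np.clip(d, lo, np.nextafter(hi, lo))
    counts, _ = np.histogram(clipped, bins=edges)
    pct = 100.0 * counts / d.size
    assert abs(pct.sum() - 100.0) < 1e-9
    return pd.DataFrame(
        {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], "percentage": pct}
    )


def enlarged_fraction_pct(
    diameters: np.ndarray, threshold_um: float = ENLARGED_THRESHOLD_UM
) -> float:
    """Percentage of spots with diameter ≥ threshold (closed comparison)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("enlarged_fraction_pct requires at least one diameter")
    return 100.0 * float(np.count_nonzero(d >= threshold_um)) / d.size


@dataclass(frozen=True)
class ColumnSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    n_missing: int = 0


def summarize_column(rows: list[CohortRow], field_name: str) -> ColumnSummary:
    """n / mean / sample-sd (n−1) / min / max of one numeric cohort column.

    Missing values (NaN) are excluded and counted.  Values are returned
    unrounded; round only when rendering reports.
    """
    values = np.asarray([getattr(r, field_name) for r in rows], dtype=float)
    missing = int(np.isnan(values).sum())
    v = values[~np.isnan(values)]
    if v.size < 2:
        raise ValueError("summarize_column needs >= 2 non-missing values")
    return ColumnSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        min=float(v.min()),
        max=float(v.max()),
        n_missing=missing,
    )


def _group_summary(name: str, x: np.ndarray) -> dict:
    return {
        "group": name,
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
    }


def t_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    variant: str = "welch",
    names: tuple[str, str] = ("A", "B"),
) -> TestResult:
    """Independent-sample t test, Welch (default) or Student variant.

    Degenerate zero-variance input: equal means → t=0, p=1; unequal means
    with zero pooled variance → error (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TestResult(
                method=f"t-test ({variant})",
                statistic=0.0,
                df=float(df),
                p_two_sided=1.0,
                group_summaries=[_group_summary(names[0], a), _group_summary(names[1], b)],
            )
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    df = float(res.df)
    return TestResult(
        method=f"t-test ({variant})",
        statistic=float(res.statistic),
        df=df,
        p_two_sided=float(res.pvalue),
        group_summaries=[_group_summary(names[0], a), _group_summary(names[1], b)],
    )


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson χ² on a 2×2 frequency table (no continuity correction by
    default; enable Yates with ``correction=True``)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = np.round(t).astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=correction)
    return TestResult(
        method="Pearson chi-square" + (" (Yates)" if correction else ""),
        statistic=float(chi2),
        df=float(dof),
        p_two_sided=float(p),
    )


def anova_tukey(
    groups: list[np.ndarray], names: list[str] | None = None
) -> tuple[TestResult, list[dict]]:
    """One-way ANOVA followed by Tukey–Kramer pairwise comparisons.

    The pairwise adjustment uses the studentized-range distribution with
    the Tukey–Kramer unequal-n standard error; for equal group sizes it
    reduces to Tukey's HSD.  Requires ≥3 groups (use :func:`t_test` for
    two).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("anova_tukey requires >= 3 groups; use t_test for 2")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    if names is None:
        names = [f"group{i}" for i in range(len(gs))]

    f_stat, p = stats.f_oneway(*gs)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    df_between = k - 1
    df_within = n_total - k
    anova = TestResult(
        method="one-way ANOVA",
        statistic=float(f_stat),
        df=float(df_between),
        p_two_sided=float(p),
        group_summaries=[_group_summary(nm, g) for nm, g in zip(names, gs)],
    )

    # pooled within-group variance (the ANOVA mean square error)
    mse = sum((g.size - 1) * g.var(ddof=1) for g in gs) / df_within
    pairwise: list[dict] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            se = math.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
            diff = a.mean() - b.mean()
            if se == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
            else:
                q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within))
            pairwise.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": min(1.0, p_adj),
                }
            )
    return anova, pairwise


@dataclass
class CohortReport:
    """Group comparison of per-eye enlarged-spot percentages."""

    per_eye: pd.DataFrame          # subject_id, group, ez_status, n_spots, enlarged_pct
    group_stats: pd.DataFrame      # group, n, mean, sd
    test: TestResult
    histograms: dict[str, pd.DataFrame]  # group -> pooled size histogram


def compare_groups(
    eyes: list[EyeRecord],
    threshold_um: float = ENLARGED_THRESHOLD_UM,
    variant: str = "welch",
    bin_width_um: float = 0.5,
    range_um: tuple[float, float] = (2.0, 9.0),
) -> CohortReport:
    """Compare control vs RP eyes on the enlarged-spot percentage.

    Computes the per-eye percentage of spots at or above the threshold,
    summarizes each group as mean ± sd, and tests the group difference
    with an independent-sample t test.
    """
    rows = []
    pooled: dict[str, list[np.ndarray]] = {"control": [], "RP": []}
    for eye in eyes:
        d = pool_eye(eye)
        rows.append(
            {
                "subject_id": eye.subject_id,
                "group": eye.group,
                "ez_status": eye.ez_status,
                "n_spots": int(d.size),
                "enlarged_pct": enlarged_fraction_pct(d, threshold_um) if d.size else float("nan"),
            }
        )
        if d.size:
            pooled[eye.group].append(d)
    per_eye = pd.DataFrame(rows)
    for g in ("control", "RP"):
        if (per_eye["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 eyes in group {g!r}")

    a = per_eye.loc[per_eye.group == "control", "enlarged_pct"].to_numpy()
    b = per_eye.loc[per_eye.group == "RP", "enlarged_pct"].to_numpy()
    test = t_test(a, b, variant=variant, names=("control", "RP"))
    group_stats = pd.DataFrame(test.group_summaries)
    histograms = {
        g: size_histogram(np.concatenate(pooled[g]), bin_width_um, range_um)
        for g in ("control", "RP")
        if pooled[g]
    }
    return CohortReport(
        per_eye=per_eye, group_stats=group_stats, test=test, histograms=histograms
    )


# ---------------------------------------------------------------------------
# cohort table I/O

_COHORT_COLUMNS = {
    "case": "case_id",
    "age": "age",
    "sex": "sex",
    "inheritance": "inheritance",
    "AL_mm": "axial_length_mm",
    "VA_logMAR": "va_logmar",
    "MD_dB": "md_db",
    "FS_dB": "fs_db",
    "EZ": "ez_status",
    "enlarged_pct": "enlarged_pct",
}


def load_cohort_csv(path: str | Path) -> list[CohortRow]:
    """Read a cohort characteristics CSV (columns: case, age, sex,
    inheritance, AL_mm, VA_logMAR, MD_dB, FS_dB, EZ, enlarged_pct)."""
    df = pd.read_csv(path, comment="#")
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    rows = []
    for r in df.itertuples():
        rows.append(
            CohortRow(
                case_id=str(r.case),
                age=float(r.age),
                sex=str(r.sex),
                inheritance=str(r.inheritance),
                axial_length_mm=float(r.AL_mm),
                va_logmar=float(r.VA_logMAR),
                md_db=float(r.MD_dB),
                fs_db=float(r.FS_dB),
                ez_status=str(r.EZ),
                enlarged_pct=float(r.enlarged_pct),
            )
        )
    return rows


def load_rp_cohort() -> list[CohortRow]:
    """The bundled ten-case RP reference cohort."""
    with resources.as_file(
        resources.files("conemosaic.data").joinpath("rp_cohort.csv")
    ) as p:
        return load_cohort_csv(p)
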