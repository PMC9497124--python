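"""Cleaning, normalization, multimodal joining and group statistics.

The assembled ``FeatureTable`` holds one row per subject with feature
columns namespaced by modality (``clinical.``, ``ntb.``, ``eeg.``,
``et.``) and labels +1 (MCI) / -1 (NC).  Four comparison views select
modality blocks: the clinical model (age, gender, education, MoCA-B,
ACE-R), the single neuropsychological model (NTB subtests), the single
physiological model (EEG + ET), and the combined model.

Normalization is two-stage — raw NTB scores min–max scaled to [0, 1],
then every assembled feature z-transformed — with all statistics fit on
training data only (the CV harness re-fits them per fold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

log = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "NormalizationParams",
    "VIEWS",
    "clean_ntb",
    "fit_apply_normalization",
    "assemble",
    "group_statistics",
]

#: modality prefixes included in each comparison view
VIEWS: dict[str, tuple[str, ...]] = {
    "clinical": ("clinical",),
    "ntb_only": ("ntb",),
    "physio_only": ("eeg", "et"),
    "all": ("clinical", "ntb", "eeg", "et"),
}

LABEL_MCI, LABEL_NC = 1, -1


@dataclass
class FeatureTable:
    """Subjects × features matrix with modality-tagged columns and labels."""

    data: pd.DataFrame  # index: subject_id; columns: "<modality>.<feature>"
    labels: pd.Series  # +1 MCI / -1 NC, same index

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels index must match data index")
        untagged = [c for c in self.data.columns if "." not in c]
        if untagged:
            raise ValueError(f"columns without modality tag: {untagged}")

    @property
    def modalities(self) -> set[str]:
        return {c.split(".", 1)[0] for c in self.data.columns}

    def view(self, name: str) -> "FeatureTable":
        if name not in VIEWS:
            raise ValueError(f"unknown view {name!r}; options: {sorted(VIEWS)}")
        prefixes = VIEWS[name]
        cols = [c for c in self.data.columns if c.split(".", 1)[0] in prefixes]
        return FeatureTable(data=self.data[cols], labels=self.labels)

    def __len__(self) -> int:
        return len(self.data)


def clean_ntb(
    table: pd.DataFrame,
    ranges: dict[str, tuple[float, float]],
    max_missing_frac: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Eliminate abnormal values and drop mostly-missing subjects.

    Cells outside the declared valid range of their subtest are set
    missing; subjects missing more than ``max_missing_frac`` of the
    range-declared columns are dropped.  Every change is logged and
    returned as a line-oriented exclusion log.
    """
    if not ranges:
        raise ValueError("no declared valid ranges")
    df = table.copy()
    exclusions: list[str] = []
    checked = [c for c in df.columns if c in ranges]
    for c in checked:
        lo, hi = ranges[c]
        bad = df[c].notna() & ((df[c] < lo) | (df[c] > hi))
        for idx in df.index[bad]:
            sid = df.loc[idx, "subject_id"] if "subject_id" in df.columns else idx
            exclusions.append(f"{sid}: {c}={df.loc[idx, c]:g} outside [{lo:g}, {hi:g}]")
        df.loc[bad, c] = np.nan
    missing_frac = df[checked].isna().mean(axis=1)
    drop = missing_frac > max_missing_frac
    for idx in df.index[drop]:
        sid = df.loc[idx, "subject_id"] if "subject_id" in df.columns else idx
        exclusions.append(
            f"{sid}: dropped ({missing_frac[idx]:.0%} of subtests missing)"
        )
    df = df.loc[~drop]
    for line in exclusions:
        log.info("NTB cleaning: %s", line)
    return df, exclusions


@dataclass
class NormalizationParams:
    """Training-population statistics of the two-stage normalization."""

    minmax: dict[str, tuple[float, float]] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    fit_population: str = ""


def fit_apply_normalization(
    train: pd.DataFrame,
    apply: pd.DataFrame | None = None,
    minmax_cols: list[str] | None = None,
    fit_population: str = "train",
) -> tuple[pd.DataFrame, pd.DataFrame | None, NormalizationParams]:
    """Fit scaling on the training table and transform both tables.

    Missing cells are median-imputed (training medians), ``minmax_cols``
    are scaled to [0, 1] with training min/max, then all columns are
    z-transformed with training mean/SD.  Columns constant in training
    are dropped with a warning.  No statistic of ``apply`` is used.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    params = NormalizationParams(fit_population=fit_population)
    tr = train.copy()
    ap = apply.copy() if apply is not None else None

    params.medians = {c: float(tr[c].median()) for c in tr.columns}
    tr = tr.fillna(params.medians)
    if ap is not None:
        ap = ap.fillna(params.medians)

    for c in minmax_cols or []:
        if c not in tr.columns:
            continue
        lo, hi = float(tr[c].min()), float(tr[c].max())
        if hi > lo:
            params.minmax[c] = (lo, hi)
            tr[c] = (tr[c] - lo) / (hi - lo)
            if ap is not None:
                ap[c] = (ap[c] - lo) / (hi - lo)

    for c in list(tr.columns):
        mu, sd = float(tr[c].mean()), float(tr[c].std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"constant column {c!r} dropped from normalization", stacklevel=2)
            params.dropped.append(c)
            tr = tr.drop(columns=[c])
            if ap is not None:
                ap = ap.drop(columns=[c])
            continue
        params.mean[c] = mu
        params.sd[c] = sd
        tr[c] = (tr[c] - mu) / sd
        if ap is not None:
            ap[c] = (ap[c] - mu) / sd
    return tr, ap, params


def _namespace(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
    out = df.copy()
    out.columns = [c if c.startswith(f"{prefix}.") else f"{prefix}.{c}" for c in out.columns]
    return out


def assemble(
    demographics: pd.DataFrame,
    ntb: pd.DataFrame | None = None,
    eeg: pd.DataFrame | None = None,
    et: pd.DataFrame | None = None,
    view: str = "all",
) -> FeatureTable:
    """Inner-join per-modality tables into one FeatureTable.

    ``demographics`` must carry ``subject_id``, ``group`` and the
    clinical variables (age, gender, education_years, moca_b, ace_r);
    gender is one-hot encoded.  Subjects absent from any required
    modality are excluded by the inner join (logged).  The ``view``
    argument selects the modality blocks of the four comparison models.
    """
    demo = demographics.set_index("subject_id")
    if demo.index.duplicated().any():
        raise ValueError("duplicated subject_id in demographics")
    labels = demo["group"].map({"MCI": LABEL_MCI, "NC": LABEL_NC})
    if labels.isna().any():
        raise ValueError("group column must contain only 'MCI'/'NC'")

    clinical = pd.DataFrame(index=demo.index)
    clinical["age"] = demo["age"]
    clinical["gender_male"] = (demo["gender"] == "male").astype(float)
    clinical["education_years"] = demo["education_years"].astype(float)
    clinical["moca_b"] = demo["moca_b"]
    clinical["ace_r"] = demo["ace_r"]
    blocks = [_namespace(clinical, "clinical")]

    for df, prefix in ((ntb, "ntb"), (eeg, "eeg"), (et, "et")):
        if df is None:
            continue
        d = df.set_index("subject_id") if "subject_id" in df.columns else df
        if d.index.duplicated().any():
            raise ValueError(f"duplicated subject_id in {prefix} table")
        drop_cols = [c for c in ("group",) if c in d.columns]
        blocks.append(_namespace(d.drop(columns=drop_cols), prefix))

    joined = pd.concat(blocks, axis=1, join="inner")
    if len(joined) == 0:
        raise ValueError("empty join: no subject present in every modality")
    lost = set(demo.index) - set(joined.index)
    if lost:
        log.info("subjects excluded by inner join: %s", ", ".join(sorted(lost)))
    table = FeatureTable(data=joined.astype(float), labels=labels.loc[joined.index])
    return table.view(view)


def group_statistics(demographics: pd.DataFrame) -> dict:
    """Between-group comparison of demographic/clinical variables.

    Continuous variables (age, MoCA-B, ACE-R) use two-sample t tests,
    gender uses a chi-square test on the 2×2 contingency table (no
    continuity correction), and education years uses the Wilcoxon
    rank-sum test.  Returns per-variable mean ± SD by group and p.
    """
    groups = demographics.groupby("group")
    if not {"NC", "MCI"} <= set(groups.groups):
        raise ValueError("both NC and MCI groups must be present")
    nc = demographics[demographics["group"] == "NC"]
    mci = demographics[demographics["group"] == "MCI"]
    if len(nc) < 2 or len(mci) < 2:
        raise ValueError("each group needs at least 2 subjects")

    report: dict[str, dict] = {}

    def cont(name: str, col: str) -> None:
        t, p = _stats.ttest_ind(nc[col], mci[col], equal_var=True)
        report[name] = {
            "nc_mean": float(nc[col].mean()),
            "nc_sd": float(nc[col].std()),
            "mci_mean": float(mci[col].mean()),
            "mci_sd": float(mci[col].std()),
            "test": "t",
            "stat": float(t),
            "p": float(p),
        }

    cont("age", "age")
    cont("moca_b", "moca_b")
    cont("ace_r", "ace_r")

    contingency = pd.crosstab(demographics["group"], demographics["gender"])
    if contingency.shape == (2, 2):
        chi2, p, _, _ = _stats.chi2_contingency(contingency, correction=False)
    else:  # a degenerate cohort with one gender only
        chi2, p = 0.0, 1.0
    report["gender"] = {
        "nc_male": int((nc["gender"] == "male").sum()),
        "nc_female": int((nc["gender"] == "female").sum()),
        "mci_male": int((mci["gender"] == "male").sum()),
        "mci_female": int((mci["gender"] == "female").sum()),
        "test": "chi2",
        "stat": float(chi2),
        "p": float(p),
    }

    w, p = _stats.ranksums(nc["education_years"], mci["education_years"])
    report["education_years"] = {
        "nc_mean": float(nc["education_years"].mean()),
        "nc_sd": float(nc["education_years"].std()),
        "mci_mean": float(mci["education_years"].mean()),
        "mci_sd": float(mci["education_years"].std()),
        "test": "wilcoxon_ranksum",
        "stat": float(w),
        "p": float(p),
    }
    return report
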