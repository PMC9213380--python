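"""Three-axis stability evaluation of radiomics features.

For every (feature, dose, reconstruction) cell of the factorial design
the pipeline scores:

* **consistency** — agreement of a feature across ROIs of the same
  tissue class at different image positions: ICC(3,1) on a rating matrix
  with subjects = the 3 tissue classes and raters = the 8 ROI positions,
  median over the repeated acquisitions; acceptable if >= 0.75;
* **discriminative power** — the Kruskal-Wallis omnibus test across the
  three tissue classes (8 values each) per repeat, Bonferroni-adjusted;
  acceptable if the adjusted p < 0.05 in >= 95% of repeats;
* **repeatability** — Barnhart's OCCC across repeated acquisitions
  (subjects = 8 ROIs, raters = repeats), computed per tissue class and
  averaged (unweighted); acceptable if >= 0.75.

A feature is **robust** in a cell when it meets all three criteria.
Undefined statistics (NaN from zero-variance features) count as failures
and are reported in dedicated columns so they remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ALL_FEATURE_NAMES, ExtractionSettings, extract_all
from .phantom import AcquisitionDesign, EmulatorParams, iter_acquisitions
from .stats import RatingMatrix, bonferroni, icc_3_1, kruskal_wallis, occc, pearson

__all__ = [
    "EvaluationThresholds",
    "simulate_and_extract",
    "consistency_analysis",
    "discriminative_analysis",
    "repeatability_analysis",
    "evaluate_stability",
    "classify_robust",
    "yield_summary",
    "robustness_grid",
    "robust_above_dose",
    "dose_yield_correlation",
]

PASS_COLUMNS = ("pass_consistency", "pass_discrimination", "pass_repeatability")


@dataclass(frozen=True)
class EvaluationThresholds:
    """Acceptance thresholds of the three stability criteria.

    ``bonferroni_family`` selects the multiplicity family for the
    Kruskal-Wallis p-values: ``"features"`` (m = number of features
    tested per cell, the conservative default), ``"none"`` (m = 1), or an
    integer for a custom family size.
    """

    icc_min: float = 0.75
    occc_min: float = 0.75
    significant_fraction_min: float = 0.95
    alpha: float = 0.05
    bonferroni_family: str | int = "features"

    def family_size(self, n_features: int) -> int:
        if self.bonferroni_family == "features":
            return n_features
        if self.bonferroni_family == "none":
            return 1
        m = int(self.bonferroni_family)
        if m < 1:
            raise ValueError("Bonferroni family size must be >= 1")
        return m


def simulate_and_extract(
    design: AcquisitionDesign,
    class_specs=None,
    shape=(4, 128, 128),
    params: EmulatorParams | None = None,
    settings: ExtractionSettings | None = None,
) -> pd.DataFrame:
    """Run the synthetic acquisition stream and extract features per ROI.

    Streams volumes one at a time (the full default design would not fit
    in memory comfortably) and returns the long-format feature table.
    """
    from .phantom import generate_ground_truth

    _, roi_set = generate_ground_truth(class_specs, shape, seed=design.master_seed)
    frames = [
        extract_all(vol, roi_set, settings, provenance=row)
        for vol, row in iter_acquisitions(design, class_specs, shape, params)
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Per-cell analyses
# ---------------------------------------------------------------------------

def _cell(features: pd.DataFrame, dose: float, recon: str) -> pd.DataFrame:
    sub = features[(features["dose_mGy"] == dose)
                   & (features["recon_mode"] == recon)]
    if sub.empty:
        raise ValueError(f"no feature rows for cell (dose={dose}, recon={recon!r})")
    return sub


def _class_matrix(sub: pd.DataFrame) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pivot one (feature, repeat) block to classes x ROI-position values."""
    classes = sorted(sub["tissue_class"].unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 tissue classes")
    rows = []
    for cls in classes:
        block = sub[sub["tissue_class"] == cls].sort_values("roi_id")
        rows.append(block["value"].to_numpy())
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("unbalanced ROI counts across tissue classes")
    return sub, classes, np.vstack(rows)


def consistency_analysis(features: pd.DataFrame, dose: float,
                         recon: str) -> pd.Series:
    """Median-over-repeats ICC(3,1) per feature for one (dose, recon) cell.

    Undefined ICCs (zero-variance features) participate in the median as
    worst-possible values; a cell whose median is itself undefined is
    reported as NaN (and therefore fails the criterion downstream).
    """
    sub = _cell(features, dose, recon)
    out = {}
    for feat, block in sub.groupby("feature", sort=False):
        iccs = []
        for _, rep_block in block.groupby("repeat"):
            _, _, mat = _class_matrix(rep_block)
            iccs.append(icc_3_1(RatingMatrix(mat)))
        arr = np.asarray(iccs, dtype=float)
        arr = np.where(np.isnan(arr), -np.inf, arr)
        med = float(np.median(arr))
        out[feat] = med if np.isfinite(med) else float("nan")
    return pd.Series(out, name="median_icc")


def discriminative_analysis(features: pd.DataFrame, dose: float, recon: str,
                            bonferroni_m: int = 1) -> pd.Series:
    """Fraction of repeats with Bonferroni-adjusted Kruskal-Wallis p < 0.05."""
    sub = _cell(features, dose, recon)
    out = {}
    for feat, block in sub.groupby("feature", sort=False):
        n_sig = 0
        n_rep = 0
        for _, rep_block in block.groupby("repeat"):
            groups = [g["value"].to_numpy()
                      for _, g in rep_block.groupby("tissue_class")]
            res = kruskal_wallis(groups)
            p_adj = float(bonferroni([res.p_value], bonferroni_m)[0])
            n_rep += 1
            n_sig += p_adj < 0.05
        out[feat] = n_sig / n_rep
    return pd.Series(out, name="kw_significant_fraction")


def repeatability_analysis(features: pd.DataFrame, dose: float,
                           recon: str) -> pd.Series:
    """Class-averaged OCCC across repeats per feature for one cell.

    Per tissue class the rating matrix has subjects = the 8 ROIs and
    raters = the repeated acquisitions; the three class OCCCs are
    averaged without weights. Any undefined class OCCC makes the mean
    NaN (a failure downstream).
    """
    sub = _cell(features, dose, recon)
    out = {}
    for feat, block in sub.groupby("feature", sort=False):
        class_occcs = []
        for _, cls_block in block.groupby("tissue_class"):
            mat = cls_block.pivot_table(index="roi_id", columns="repeat",
                                        values="value", sort=True)
            class_occcs.append(occc(RatingMatrix(mat.to_numpy())))
        out[feat] = float(np.mean(class_occcs))
    return pd.Series(out, name="mean_occc")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluate_stability(features: pd.DataFrame,
                       thresholds: EvaluationThresholds | None = None
                       ) -> pd.DataFrame:
    """Full stability report: one row per (feature, dose, recon) cell."""
    th = thresholds or EvaluationThresholds()
    cells = (features[["dose_mGy", "recon_mode"]]
             .drop_duplicates().sort_values(["recon_mode", "dose_mGy"]))
    n_features = features["feature"].nunique()
    m = th.family_size(n_features)
    rows = []
    for dose, recon in cells.itertuples(index=False):
        icc = consistency_analysis(features, dose, recon)
        kw = discriminative_analysis(features, dose, recon, bonferroni_m=m)
        oc = repeatability_analysis(features, dose, recon)
        cell = pd.DataFrame({"median_icc": icc,
                             "kw_significant_fraction": kw,
                             "mean_occc": oc})
        cell.insert(0, "recon_mode", recon)
        cell.insert(0, "dose_mGy", dose)
        cell.index.name = "feature"
        rows.append(cell.reset_index())
    report = pd.concat(rows, ignore_index=True)
    return classify_robust(report, th)


def classify_robust(report: pd.DataFrame,
                    thresholds: EvaluationThresholds | None = None
                    ) -> pd.DataFrame:
    """Attach the three pass flags and the combined robust flag.

    NaN statistics compare as failing (a feature that is constant
    everywhere carries no information and must not be scored stable).
    """
    th = thresholds or EvaluationThresholds()
    rep = report.copy()
    with np.errstate(invalid="ignore"):
        rep["pass_consistency"] = rep["median_icc"].to_numpy() >= th.icc_min
        rep["pass_discrimination"] = (
            rep["kw_significant_fraction"].to_numpy()
            >= th.significant_fraction_min
        )
        rep["pass_repeatability"] = rep["mean_occc"].to_numpy() >= th.occc_min
    rep["undefined_icc"] = rep["median_icc"].isna()
    rep["undefined_occc"] = rep["mean_occc"].isna()
    rep["robust"] = (rep["pass_consistency"] & rep["pass_discrimination"]
                     & rep["pass_repeatability"])
    return rep


def yield_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Fraction of features passing each criterion per (dose, recon) cell."""
    grouped = report.groupby(["recon_mode", "dose_mGy"])
    out = grouped[list(PASS_COLUMNS) + ["robust"]].mean()
    out.columns = ["fraction_consistent", "fraction_discriminative",
                   "fraction_repeatable", "fraction_robust"]
    return out.reset_index()


def robustness_grid(report: pd.DataFrame, recon: str) -> pd.DataFrame:
    """Feature x dose boolean grid of the robust flag for one reconstruction."""
    sub = report[report["recon_mode"] == recon]
    return sub.pivot_table(index="feature", columns="dose_mGy",
                           values="robust", aggfunc="first").astype(bool)


def robust_above_dose(report: pd.DataFrame, recon: str,
                      dose_min: float, strict: bool = True) -> list[str]:
    """Features robust at *every* dose above (or at) ``dose_min``."""
    grid = robustness_grid(report, recon)
    doses = grid.columns[(grid.columns > dose_min) if strict
                         else (grid.columns >= dose_min)]
    if len(doses) == 0:
        return []
    sel = grid[doses].all(axis=1)
    return sorted(grid.index[sel])


def dose_yield_correlation(summary: pd.DataFrame, recon: str,
                           criterion: str = "fraction_repeatable"):
    """Pearson correlation of dose against the per-dose feature yield."""
    sub = summary[summary["recon_mode"] == recon].sort_values("dose_mGy")
    if len(sub) < 3:
        raise ValueError("need >= 3 dose points for a correlation")
    return pearson(sub["dose_mGy"].to_numpy(), sub[criterion].to_numpy())


def summary_statistics(summary: pd.DataFrame) -> pd.DataFrame:
    """Per reconstruction: median and range over doses of each yield fraction."""
    rows = []
    for recon, sub in summary.groupby("recon_mode"):
        row = {"recon_mode": recon}
        for col in ("fraction_consistent", "fraction_discriminative",
                    "fraction_repeatable", "fraction_robust"):
            row[f"{col}_median"] = float(sub[col].median())
            row[f"{col}_min"] = float(sub[col].min())
            row[f"{col}_max"] = float(sub[col].max())
        rows.append(row)
    return pd.DataFrame(rows)
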