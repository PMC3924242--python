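"""Comparative LFQ proteomics of clathrin-coated-structure fractions.

Starting from a MaxQuant-style ``proteinGroups.txt`` table with per-sample
label-free quantitation (LFQ) intensities, this module computes each
protein group's interphase/mitotic abundance ratio, fits a single
Gaussian to the frequency histogram of log2 ratios (the null describing
unregulated proteins), and calls as outliers the proteins whose log2
ratio lies beyond mu +/- 2 sigma of the fitted null.  Proteins whose LFQ
value is zero in one condition are excluded from the ratio analysis;
those with a large intensity (> 1e6 by default) on the nonzero side are
classified as condition-exclusive, a plausible sign of genuine all-or-
nothing regulation rather than poor detection.

The analysis is exposed both as plain functions and as a model/results
pair: ``CcsRatioModel(table).fit()`` returns a ``CcsRatioResults`` object
carrying the ratio table, the fitted null and the outlier calls, with
``summary()``, per-experiment consistency and reference-list annotation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ProteinQuantTable",
    "GaussianFit",
    "GaussianFitError",
    "CcsRatioModel",
    "CcsRatioResults",
    "ConsistencyResult",
    "read_protein_groups",
    "compute_ratios",
    "fit_gaussian_null",
    "call_outliers",
    "per_experiment_consistency",
    "annotate",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("interphase", "mitotic")
CONTAMINANT_PREFIXES = ("CON__", "REV__")

STATUS_OK = "ratio_ok"
STATUS_EXCLUDED = "excluded_zero"
STATUS_INTERPHASE_EXCL = "interphase_exclusive"
STATUS_MITOTIC_EXCL = "mitotic_exclusive"

CALL_NONE = "none"
CALL_INTERPHASE = "interphase_enriched"
CALL_MITOTIC = "mitotic_enriched"


class GaussianFitError(RuntimeError):
    """Gaussian histogram fit failed; carries the moment-based initial
    estimates so the caller can fall back on them."""

    def __init__(self, message: str, initial: tuple[float, float]):
        super().__init__(f"{message} (initial estimates mu={initial[0]:.4g}, sigma={initial[1]:.4g})")
        self.initial = initial


@dataclass
class ProteinQuantTable:
    """A parsed protein-group quantitation table.

    ``condition_columns`` maps each condition to ``{experiment_label:
    column_name}``; a combined-analysis column without an experiment
    suffix is stored under the key ``"combined"``.
    """

    data: pd.DataFrame
    condition_columns: dict[str, dict[str, str]]
    n_dropped_contaminants: int = 0

    def __post_init__(self) -> None:
        if self.data["Protein IDs"].duplicated().any():
            dupes = self.data.loc[self.data["Protein IDs"].duplicated(), "Protein IDs"]
            raise ValueError(f"duplicate protein ids: {sorted(set(dupes))}")
        lfq_cols = [c for cols in self.condition_columns.values() for c in cols.values()]
        neg = (self.data[lfq_cols] < 0).any().any()
        if neg:
            raise ValueError("negative LFQ intensity values are not allowed")

    @property
    def experiments(self) -> list[str]:
        exps: list[str] = []
        for cols in self.condition_columns.values():
            for e in cols:
                if e != "combined" and e not in exps:
                    exps.append(e)
        return exps

    def condition_value(self, condition: str, experiment: str | None = None) -> pd.Series:
        """Per-protein LFQ value for one condition.

        With ``experiment`` given, the single per-experiment column.
        Otherwise the combined-analysis column when present, else the
        mean over nonzero per-experiment values (0 when all are zero).
        """
        cols = self.condition_columns[condition]
        if experiment is not None:
            return self.data[cols[experiment]].astype(float)
        if "combined" in cols:
            return self.data[cols["combined"]].astype(float)
        exp_cols = [cols[e] for e in self.experiments if e in cols]
        mat = self.data[exp_cols].to_numpy(dtype=float)
        nonzero = mat > 0
        # mean over nonzero experiments only; 0 when all experiments are 0
        sums = np.where(nonzero, mat, 0.0).sum(axis=1)
        counts = nonzero.sum(axis=1)
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        return pd.Series(vals, index=self.data.index)


def _parse_lfq_columns(columns: Iterable[str]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for col in columns:
        if not col.startswith("LFQ intensity "):
            continue
        rest = col[len("LFQ intensity "):]
        for cond in CONDITIONS:
            if rest == cond:
                out.setdefault(cond, {})["combined"] = col
            elif rest.startswith(cond + "_"):
                out.setdefault(cond, {})[rest[len(cond) + 1:]] = col
    return out


def read_protein_groups(
    path_or_df: str | Path | pd.DataFrame,
    condition_column_map: Mapping[str, Mapping[str, str]] | None = None,
) -> ProteinQuantTable:
    """Read a tab-separated proteinGroups table.

    Contaminant and reverse-decoy rows (``Protein IDs`` prefixed
    ``CON__``/``REV__``) are dropped, with the count logged.  LFQ columns
    are auto-detected from the ``LFQ intensity <condition>[_<exp>]``
    naming unless an explicit map is given.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    if "Protein IDs" not in df.columns:
        raise ValueError("table lacks a 'Protein IDs' column")
    if "Gene names" not in df.columns:
        df["Gene names"] = df["Protein IDs"]

    is_con = df["Protein IDs"].astype(str).str.startswith(CONTAMINANT_PREFIXES)
    n_dropped = int(is_con.sum())
    if n_dropped:
        logger.info("dropped %d contaminant/decoy rows", n_dropped)
    df = df.loc[~is_con].reset_index(drop=True)

    if condition_column_map is not None:
        cond_cols = {c: dict(m) for c, m in condition_column_map.items()}
    else:
        cond_cols = _parse_lfq_columns(df.columns)

    missing = [c for c in CONDITIONS if c not in cond_cols or not cond_cols[c]]
    absent_cols = [
        col for m in cond_cols.values() for col in m.values() if col not in df.columns
    ]
    if missing or absent_cols:
        raise ValueError(
            f"missing LFQ columns: conditions without columns {missing}, "
            f"mapped columns absent from file {absent_cols}"
        )
    return ProteinQuantTable(df, cond_cols, n_dropped)


def compute_ratios(
    table: ProteinQuantTable,
    exclusive_threshold: float = 1e6,
    experiment: str | None = None,
) -> pd.DataFrame:
    """Interphase/mitotic LFQ ratios with status classification.

    Status per protein: ``ratio_ok`` when both condition values are
    positive; otherwise ``excluded_zero``, refined to
    ``interphase_exclusive``/``mitotic_exclusive`` when the nonzero side
    exceeds ``exclusive_threshold``.  ``log2_ratio`` is defined only for
    ``ratio_ok`` rows.
    """
    inter = table.condition_value("interphase", experiment).to_numpy(dtype=float)
    mito = table.condition_value("mitotic", experiment).to_numpy(dtype=float)

    status = np.full(inter.shape, STATUS_OK, dtype=object)
    both_pos = (inter > 0) & (mito > 0)
    status[~both_pos] = STATUS_EXCLUDED
    status[(mito == 0) & (inter > exclusive_threshold)] = STATUS_INTERPHASE_EXCL
    status[(inter == 0) & (mito > exclusive_threshold)] = STATUS_MITOTIC_EXCL

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(both_pos, inter / np.where(mito > 0, mito, np.nan), np.nan)
        log2_ratio = np.where(both_pos, np.log2(np.where(both_pos, ratio, np.nan)), np.nan)

    return pd.DataFrame(
        {
            "protein_id": table.data["Protein IDs"].to_numpy(),
            "gene_name": table.data["Gene names"].to_numpy(),
            "interphase_lfq": inter,
            "mitotic_lfq": mito,
            "ratio": ratio,
            "log2_ratio": log2_ratio,
            "status": status,
            "outlier_call": CALL_NONE,
        }
    )


@dataclass(frozen=True)
class GaussianFit:
    """Fitted Gaussian null of the log2-ratio histogram."""

    mu: float
    sigma: float
    amplitude: float
    bin_width: float
    n_fitted: int
    goodness: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def lower(self) -> float:
        return self.mu - 2.0 * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + 2.0 * self.sigma


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_null(
    log2_ratios: Iterable[float] | pd.DataFrame,
    bin_width: float = 0.25,
    method: str = "lsq",
    min_proteins: int = 50,
) -> GaussianFit:
    """Fit a single Gaussian to the frequency histogram of log2 ratios.

    ``method="lsq"`` (default) least-squares fits ``amp * exp(-(x-mu)^2 /
    (2 sigma^2))`` to the bin counts, initialised at the sample moments;
    ``method="moments"`` returns the sample mean/SD directly.  A
    ``DataFrame`` from :func:`compute_ratios` may be passed, in which case
    only ``ratio_ok`` rows are used.
    """
    if isinstance(log2_ratios, pd.DataFrame):
        x = log2_ratios.loc[log2_ratios["status"] == STATUS_OK, "log2_ratio"]
    else:
        x = pd.Series(list(log2_ratios), dtype=float)
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_proteins:
        raise ValueError(f"need >= {min_proteins} ratio_ok proteins, got {x.size}")

    mu0, sd0 = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd0 == 0:
        raise GaussianFitError("degenerate ratios: zero spread", (mu0, sd0))

    if method == "moments":
        return GaussianFit(mu0, sd0, float("nan"), bin_width, int(x.size), {"method": "moments"})
    if method != "lsq":
        raise ValueError(f"unknown method {method!r}")

    lo = math.floor(x.min() / bin_width) * bin_width
    hi = math.ceil(x.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    p0 = (float(counts.max()), mu0, sd0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise GaussianFitError(f"Gaussian fit did not converge: {err}", (mu0, sd0)) from err
    amp, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if sigma <= 0 or not np.isfinite(sigma):
        raise GaussianFitError("fit returned a degenerate sigma", (mu0, sd0))

    resid = counts - _gauss(centers, amp, mu, sigma)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    rss = float(np.sum(resid**2))
    goodness = {
        "rss": rss,
        "r2": 1.0 - rss / ss_tot if ss_tot > 0 else float("nan"),
        "n_bins": int(counts.size),
    }
    return GaussianFit(mu, sigma, amp, bin_width, int(x.size), goodness)


def call_outliers(ratios: pd.DataFrame, fit: GaussianFit) -> pd.DataFrame:
    """Set ``outlier_call`` beyond mu +/- 2 sigma (strict inequality).

    Returns a copy; only ``ratio_ok`` rows can be called.
    """
    out = ratios.copy()
    ok = out["status"] == STATUS_OK
    out["outlier_call"] = CALL_NONE
    out.loc[ok & (out["log2_ratio"] > fit.upper), "outlier_call"] = CALL_INTERPHASE
    out.loc[ok & (out["log2_ratio"] < fit.lower), "outlier_call"] = CALL_MITOTIC
    return out


@dataclass
class ConsistencyResult:
    """Outlier sets per experiment, their intersection, and per-protein
    consistency counts (how many analysed experiments flagged each)."""

    per_experiment: dict[str, pd.DataFrame]
    outlier_sets: dict[str, set[str]]
    intersection: set[str]
    counts: pd.Series
    n_experiments: int

    def consistency(self, protein_id: str) -> tuple[int, int]:
        return int(self.counts.get(protein_id, 0)), self.n_experiments


def per_experiment_consistency(
    table: ProteinQuantTable,
    exclusive_threshold: float = 1e6,
    bin_width: float = 0.25,
    min_proteins: int = 50,
) -> ConsistencyResult:
    """Run the ratio -> fit -> call chain for each experiment separately.

    Experiments with fewer than ``min_proteins`` ratio_ok proteins are
    skipped with a warning.
    """
    experiments = table.experiments
    if len(experiments) < 2:
        raise ValueError("per-experiment consistency needs >= 2 experiments")
    per_exp: dict[str, pd.DataFrame] = {}
    sets: dict[str, set[str]] = {}
    for e in experiments:
        ratios = compute_ratios(table, exclusive_threshold, experiment=e)
        n_ok = int((ratios["status"] == STATUS_OK).sum())
        if n_ok < min_proteins:
            warnings.warn(
                f"experiment {e!r} skipped: only {n_ok} ratio_ok proteins",
                stacklevel=2,
            )
            continue
        fit = fit_gaussian_null(ratios, bin_width=bin_width, min_proteins=min_proteins)
        called = call_outliers(ratios, fit)
        per_exp[e] = called
        sets[e] = set(called.loc[called["outlier_call"] != CALL_NONE, "protein_id"])
    if not sets:
        raise ValueError("no experiment had enough ratio_ok proteins")
    inter = set.intersection(*sets.values())
    all_ids = sorted(set().union(*sets.values()))
    counts = pd.Series(
        {pid: sum(pid in s for s in sets.values()) for pid in all_ids}, dtype=int
    )
    return ConsistencyResult(per_exp, sets, inter, counts, len(sets))


def annotate(
    ratios: pd.DataFrame,
    reference_lists: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Restrict/label ratios by reference-list membership.

    ``reference_lists`` maps a label (e.g. ``"ccs_core"``,
    ``"actin_related"``) to protein/gene identifiers.  Rows matching at
    least one list (on protein id or gene name) are returned with a
    ``labels`` column, ordered by descending log2 ratio; rows in several
    lists carry all labels.
    """
    sets = {}
    for name, ids in reference_lists.items():
        s = {str(i) for i in ids}
        if not s:
            raise ValueError(f"reference list {name!r} is empty")
        sets[name] = s
    labels = []
    for _, row in ratios.iterrows():
        row_labels = [
            name for name, s in sets.items()
            if row["protein_id"] in s or row["gene_name"] in s
        ]
        labels.append(";".join(row_labels))
    out = ratios.copy()
    out["labels"] = labels
    out = out[out["labels"] != ""]
    return out.sort_values("log2_ratio", ascending=False, na_position="last").reset_index(drop=True)


def load_reference_list(path: str | Path) -> set[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


# ---------------------------------------------------------------------------
# Model / results interface


class CcsRatioModel:
    """Interphase/mitotic LFQ ratio analysis of a protein-group table.

    Parameters
    ----------
    table : ProteinQuantTable
        Parsed quantitation table (see :func:`read_protein_groups`).
    exclusive_threshold : float
        LFQ value above which a one-condition-only protein is classified
        as condition-exclusive rather than excluded (default 1e6).
    bin_width : float
        Histogram bin width for the Gaussian null fit, log2 units
        (default 0.25).
    """

    def __init__(
        self,
        table: ProteinQuantTable,
        exclusive_threshold: float = 1e6,
        bin_width: float = 0.25,
    ):
        self.table = table
        self.exclusive_threshold = exclusive_threshold
        self.bin_width = bin_width

    @classmethod
    def from_file(cls, path: str | Path, condition_column_map=None, **kwargs) -> "CcsRatioModel":
        return cls(read_protein_groups(path, condition_column_map), **kwargs)

    def fit(self, method: str = "lsq") -> "CcsRatioResults":
        ratios = compute_ratios(self.table, self.exclusive_threshold)
        null_fit = fit_gaussian_null(ratios, bin_width=self.bin_width, method=method)
        ratios = call_outliers(ratios, null_fit)
        return CcsRatioResults(self, ratios, null_fit)


class CcsRatioResults:
    """Results of a :class:`CcsRatioModel` fit.

    Attributes
    ----------
    ratios : DataFrame
        One row per protein group with condition LFQ values, ratio,
        log2 ratio, status and outlier call.
    null_fit : GaussianFit
        The fitted Gaussian null (mu, sigma) of the log2-ratio histogram.
    """

    def __init__(self, model: CcsRatioModel, ratios: pd.DataFrame, null_fit: GaussianFit):
        self.model = model
        self.ratios = ratios
        self.null_fit = null_fit

    @property
    def outliers(self) -> pd.DataFrame:
        return self.ratios[self.ratios["outlier_call"] != CALL_NONE]

    @property
    def exclusives(self) -> dict[str, list[str]]:
        r = self.ratios
        return {
            "interphase": sorted(r.loc[r["status"] == STATUS_INTERPHASE_EXCL, "protein_id"]),
            "mitotic": sorted(r.loc[r["status"] == STATUS_MITOTIC_EXCL, "protein_id"]),
        }

    def per_experiment_consistency(self, **kwargs) -> ConsistencyResult:
        return per_experiment_consistency(
            self.model.table,
            exclusive_threshold=self.model.exclusive_threshold,
            bin_width=self.model.bin_width,
            **kwargs,
        )

    def annotate(self, reference_lists: Mapping[str, Iterable[str]]) -> pd.DataFrame:
        return annotate(self.ratios, reference_lists)

    def summary(self) -> str:
        r = self.ratios
        fit = self.null_fit
        counts = r["status"].value_counts()
        lines = [
            "Interphase/mitotic LFQ ratio analysis",
            "=" * 45,
            f"protein groups analysed : {len(r)}",
            f"  ratio_ok              : {counts.get(STATUS_OK, 0)}",
            f"  excluded_zero         : {counts.get(STATUS_EXCLUDED, 0)}",
            f"  interphase_exclusive  : {counts.get(STATUS_INTERPHASE_EXCL, 0)}",
            f"  mitotic_exclusive     : {counts.get(STATUS_MITOTIC_EXCL, 0)}",
            "",
            f"Gaussian null (log2 ratio histogram, bin {fit.bin_width:g}):",
            f"  mu = {fit.mu:.4f}, sigma = {fit.sigma:.4f}  "
            f"(outlier bounds {fit.lower:.3f} .. {fit.upper:.3f})",
            f"  fit r^2 = {fit.goodness.get('r2', float('nan')):.4f} over "
            f"{fit.goodness.get('n_bins', 0)} bins",
            "",
            f"outliers: {int((r['outlier_call'] == CALL_INTERPHASE).sum())} interphase-enriched, "
            f"{int((r['outlier_call'] == CALL_MITOTIC).sum())} mitotic-enriched",
        ]
        top = self.outliers.sort_values("log2_ratio", ascending=False)
        if len(top):
            lines.append("  strongest (by |log2 ratio|):")
            show = pd.concat([top.head(3), top.tail(3)]).drop_duplicates("protein_id")
            for _, row in show.iterrows():
                lines.append(
                    f"    {row['gene_name']:<12} ratio {row['ratio']:8.3f} "
                    f"log2 {row['log2_ratio']:7.3f}  {row['outlier_call']}"
                )
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        """Log2-ratio histogram with the fitted Gaussian and the
        +/- 2 sigma band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.ratios.loc[self.ratios["status"] == STATUS_OK, "log2_ratio"].dropna()
        fit = self.null_fit
        lo = math.floor(x.min() / fit.bin_width) * fit.bin_width
        hi = math.ceil(x.max() / fit.bin_width) * fit.bin_width
        edges = np.arange(lo, hi + fit.bin_width / 2, fit.bin_width)
        ax.hist(x, bins=edges, color="0.7", label="log2 ratios")
        grid = np.linspace(lo, hi, 400)
        ax.plot(grid, _gauss(grid, fit.amplitude, fit.mu, fit.sigma), "k-", label="Gaussian fit")
        ax.axvspan(fit.lower, fit.upper, color="tab:blue", alpha=0.15, label="mu +/- 2 sigma")
        ax.set_xlabel("log2(interphase / mitotic LFQ)")
        ax.set_ylabel("frequency")
        ax.legend()
        return ax
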