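"""Binding-panel selectivity statistics.

A kinase x inhibitor panel of dissociation constants (Kd, nM) is reduced to:

* hit rates — the number of inhibitors binding a kinase with Kd strictly
  below a cutoff (default 10 uM = 10000 nM);
* selective / promiscuous labels from a hit-rate threshold (default 10);
* finite-sampling randomization — repeatedly drawing small inhibitor subsets
  and counting apparently-selective kinases, quantifying how small panels
  overestimate selectivity;
* ROC/AUC of the threading score as a classifier of the labels;
* score-binned summaries: mean hit rates per group and strong/average/weak
  affinity-class fractions per bin;
* precision-recall evaluation of an external predicted-affinity table.

Censoring: a reported Kd equal to the panel's censor value (default 10000 nM)
means "no binding detected at the assay ceiling"; censored entries never
count as hits at any cutoff.  Never-assayed pairs are stored as NaN and are
excluded from denominators — missing is distinct from censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from pottsthread.threadscore import PROMISCUOUS, SELECTIVE

DEFAULT_CENSOR_NM = 10000.0
DEFAULT_HIT_CUTOFF_NM = 10000.0
DEFAULT_SELECTIVITY_THRESHOLD = 10

STRONG, AVERAGE, WEAK = "strong", "average", "weak"

#: affinity regimes used for per-regime predictor evaluation:
#: (name, lower-exclusive, upper-inclusive) in nM.  The first two are nested
#: on purpose — very strong binders are a subset of strong binders.
DEFAULT_REGIMES = (
    ("Kd<=10", 0.0, 10.0),
    ("Kd<=100", 0.0, 100.0),
    ("100<Kd<=5000", 100.0, 5000.0),
    ("Kd>5000", 5000.0, np.inf),
)


@dataclass
class BindingPanel:
    """Kd matrix (nM) with explicit censoring and missingness.

    ``kd[i, j]`` is the measured Kd of inhibitor j against kinase i; NaN
    marks a never-assayed pair, and ``censored[i, j]`` marks measurements
    reported at the assay ceiling (no binding detected).
    """

    kinases: list[str]
    inhibitors: list[str]
    datasets: list[str]
    kd: np.ndarray
    censored: np.ndarray = None
    censor_value: float = DEFAULT_CENSOR_NM

    def __post_init__(self) -> None:
        self.kd = np.asarray(self.kd, dtype=np.float64)
        nk, ni = len(self.kinases), len(self.inhibitors)
        if self.kd.shape != (nk, ni):
            raise ValueError(f"kd must be ({nk}, {ni}), got {self.kd.shape}")
        if len(self.datasets) != ni:
            raise ValueError("one dataset tag per inhibitor required")
        if len(set(self.kinases)) != nk or len(set(self.inhibitors)) != ni:
            raise ValueError("kinase and inhibitor ids must be unique")
        measured = ~np.isnan(self.kd)
        if measured.any() and np.nanmin(self.kd) <= 0:
            raise ValueError("measured Kd values must be positive")
        if self.censored is None:
            self.censored = measured & (self.kd >= self.censor_value)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.censored.shape != self.kd.shape:
            raise ValueError("censored mask must match kd shape")
        if (self.censored & ~measured).any():
            raise ValueError("a missing measurement cannot be censored")

    @property
    def measured(self) -> np.ndarray:
        return ~np.isnan(self.kd)

    def kinase_index(self, kinase: str) -> int:
        try:
            return self.kinases.index(kinase)
        except ValueError:
            raise KeyError(f"unknown kinase {kinase!r}") from None

    def inhibitor_indices(self, inhibitors: list[str] | None) -> np.ndarray:
        if inhibitors is None:
            return np.arange(len(self.inhibitors))
        idx = []
        for inh in inhibitors:
            try:
                idx.append(self.inhibitors.index(inh))
            except ValueError:
                raise KeyError(f"unknown inhibitor {inh!r}") from None
        return np.asarray(idx, dtype=int)

    def subset_by_dataset(self, dataset: str) -> list[str]:
        return [inh for inh, d in zip(self.inhibitors, self.datasets) if d == dataset]


def hit_matrix(panel: BindingPanel, kd_cutoff_nM: float = DEFAULT_HIT_CUTOFF_NM) -> np.ndarray:
    """Boolean kinase x inhibitor matrix of hits (measured, uncensored, Kd < cutoff)."""
    if kd_cutoff_nM <= 0:
        raise ValueError("kd cutoff must be positive")
    with np.errstate(invalid="ignore"):
        return panel.measured & ~panel.censored & (panel.kd < kd_cutoff_nM)


def hit_rate(
    panel: BindingPanel,
    kinase: str,
    inhibitor_subset: list[str] | None = None,
    kd_cutoff_nM: float = DEFAULT_HIT_CUTOFF_NM,
) -> int:
    """Number of inhibitors in the subset binding the kinase with Kd < cutoff."""
    cols = panel.inhibitor_indices(inhibitor_subset)
    if cols.size == 0:
        raise ValueError("inhibitor subset must be non-empty")
    row = panel.kinase_index(kinase)
    return int(hit_matrix(panel, kd_cutoff_nM)[row, cols].sum())


def hit_rates(
    panel: BindingPanel,
    inhibitor_subset: list[str] | None = None,
    kd_cutoff_nM: float = DEFAULT_HIT_CUTOFF_NM,
) -> pd.Series:
    """Per-kinase hit counts over the subset (index = kinase id)."""
    cols = panel.inhibitor_indices(inhibitor_subset)
    counts = hit_matrix(panel, kd_cutoff_nM)[:, cols].sum(axis=1)
    return pd.Series(counts, index=panel.kinases, name="hit_rate")


def label_selectivity(
    rates: pd.Series | np.ndarray,
    selectivity_threshold: int = DEFAULT_SELECTIVITY_THRESHOLD,
) -> pd.Series:
    """hit rate <= threshold -> selective, else promiscuous."""
    if selectivity_threshold < 0:
        raise ValueError("selectivity threshold must be non-negative")
    rates = pd.Series(rates)
    return rates.le(selectivity_threshold).map({True: SELECTIVE, False: PROMISCUOUS})


def subset_randomization(
    panel: BindingPanel,
    k: int,
    iterations: int,
    hit_rate_ceilings: list[int],
    pool: list[str] | None = None,
    seed: int = 0,
    kd_cutoff_nM: float = DEFAULT_HIT_CUTOFF_NM,
) -> pd.DataFrame:
    """Finite-sampling randomization of inhibitor subsets.

    Repeatedly (``iterations`` times) draws ``k`` inhibitors uniformly without
    replacement from ``pool`` (default: all inhibitors) and, for each draw,
    counts kinases whose hit rate over the drawn subset is <= each ceiling.
    Returns per-ceiling mean and standard deviation of those counts, plus the
    corresponding full-pool counts for reference.
    """
    cols = panel.inhibitor_indices(pool)
    if k > cols.size:
        raise ValueError(f"k = {k} exceeds pool size {cols.size}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    hm = hit_matrix(panel, kd_cutoff_nM)[:, cols]
    ceilings = np.asarray(hit_rate_ceilings, dtype=int)
    counts = np.empty((iterations, ceilings.size))
    for it in range(iterations):
        pick = rng.choice(cols.size, size=k, replace=False)
        rates = hm[:, pick].sum(axis=1)
        counts[it] = (rates[:, None] <= ceilings[None, :]).sum(axis=0)
    full_rates = hm.sum(axis=1)
    n_kin = len(panel.kinases)
    return pd.DataFrame(
        {
            "ceiling": ceilings,
            "mean_count": counts.mean(axis=0),
            "sd_count": counts.std(axis=0, ddof=0),
            "mean_percent": 100.0 * counts.mean(axis=0) / n_kin,
            "full_pool_count": [
                int((full_rates <= c).sum()) for c in ceilings
            ],
        }
    )


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    best_cutoff: float


def roc_auc(scores, labels) -> RocResult:
    """ROC of a score predicting the selective class (higher score => selective).

    AUC is the trapezoidal area, identical to the tie-corrected Mann-Whitney
    rank statistic; the best operating cutoff maximizes Youden's J = TPR - FPR.
    """
    scores = np.asarray(pd.Series(scores).to_numpy(), dtype=float)
    y = np.asarray([1 if l == SELECTIVE else 0 for l in labels])
    if y.shape != scores.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("both selective and promiscuous labels are required")
    fpr, tpr, thr = roc_curve(y, scores)
    area = float(_sk_auc(fpr, tpr))
    best = int(np.argmax(tpr - fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=area,
                     best_cutoff=float(thr[best]))


def bin_by_score(
    scores: pd.Series,
    values: pd.Series,
    group_size: int,
) -> pd.DataFrame:
    """Sort by score descending, chunk into consecutive groups, average within.

    The final partial group (if any) is kept and flagged in the ``partial``
    column.  Used e.g. to average hit rates within groups of 25 kinases so the
    score-vs-hit-rate trend is visible through the noise.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    scores = pd.Series(scores)
    values = pd.Series(values).reindex(scores.index)
    order = np.argsort(-scores.to_numpy(), kind="stable")
    s = scores.to_numpy()[order]
    v = values.to_numpy()[order]
    rows = []
    for g, start in enumerate(range(0, len(s), group_size)):
        sl = slice(start, start + group_size)
        rows.append(
            {
                "group": g,
                "n": len(s[sl]),
                "mean_score": float(np.mean(s[sl])),
                "mean_value": float(np.mean(v[sl])),
                "partial": len(s[sl]) < group_size,
            }
        )
    return pd.DataFrame(rows)


def affinity_class(kd_nM: float) -> str:
    """strong (Kd < 100 nM), average (100 <= Kd <= 5000), weak (Kd > 5000).

    Kd exactly 100 nM is assigned to the average class (documented closure of
    the boundary left open by the strict definitions); Kd exactly 5000 is
    average.
    """
    if not kd_nM > 0:
        raise ValueError("Kd must be positive")
    if kd_nM < 100.0:
        return STRONG
    if kd_nM <= 5000.0:
        return AVERAGE
    return WEAK


def affinity_classes(kd_nM: np.ndarray) -> np.ndarray:
    """Vectorized :func:`affinity_class`."""
    kd = np.asarray(kd_nM, dtype=float)
    if np.any(kd[~np.isnan(kd)] <= 0):
        raise ValueError("Kd must be positive")
    out = np.where(kd < 100.0, STRONG, np.where(kd <= 5000.0, AVERAGE, WEAK))
    return np.where(np.isnan(kd), "", out)


def most_promiscuous(
    panel: BindingPanel,
    n: int = 4,
    kd_cutoff_nM: float = DEFAULT_HIT_CUTOFF_NM,
) -> list[str]:
    """Top-n inhibitors by total hits across the panel (ties broken by order)."""
    totals = hit_matrix(panel, kd_cutoff_nM).sum(axis=0)
    order = np.argsort(-totals, kind="stable")[:n]
    return [panel.inhibitors[i] for i in order]


def binned_affinity_distribution(
    panel: BindingPanel,
    scores: pd.Series,
    inhibitors: list[str] | None = None,
    bin_size: int = 35,
) -> pd.DataFrame:
    """Strong/average/weak fractions per threading-score bin.

    Kinases are sorted by score descending and chunked into bins of
    ``bin_size``; within each bin all measured kinase-inhibitor pairs for the
    chosen inhibitors (default: the 4 most promiscuous) are classified by
    affinity and the per-class fractions reported (they sum to 1 per bin;
    censored measurements fall in the weak class).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if inhibitors is None:
        inhibitors = most_promiscuous(panel, n=4)
    cols = panel.inhibitor_indices(inhibitors)
    scores = pd.Series(scores).reindex(panel.kinases)
    if scores.isna().any():
        missing = list(scores.index[scores.isna()])
        raise ValueError(f"no score for kinase(s): {', '.join(missing)}")
    order = np.argsort(-scores.to_numpy(), kind="stable")
    rows = []
    for b, start in enumerate(range(0, len(order), bin_size)):
        rows_idx = order[start:start + bin_size]
        kd = panel.kd[np.ix_(rows_idx, cols)]
        kd = kd[~np.isnan(kd)]
        n_pairs = kd.size
        if n_pairs:
            cls = affinity_classes(kd)
            fs = float((cls == STRONG).mean())
            fa = float((cls == AVERAGE).mean())
            fw = float((cls == WEAK).mean())
        else:
            fs = fa = fw = np.nan
        rows.append(
            {
                "bin": b,
                "n_kinases": len(rows_idx),
                "n_pairs": n_pairs,
                "mean_score": float(scores.to_numpy()[rows_idx].mean()),
                "frac_strong": fs,
                "frac_average": fa,
                "frac_weak": fw,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PredictionEvaluation:
    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    regimes: pd.DataFrame
    binder_cutoff_nM: float
    prevalence: float


def evaluate_predictions(
    truth: BindingPanel,
    predicted: BindingPanel,
    binder_cutoff_nM: float = 100.0,
    regimes=DEFAULT_REGIMES,
) -> PredictionEvaluation:
    """Precision-recall and per-regime true-positive rates of a predictor.

    Ground truth is binary binding at ``binder_cutoff_nM`` (Kd <= cutoff,
    censored pairs never binders); predicted affinities rank the pairs (lower
    predicted Kd first).  AUPR is the trapezoidal area over the PR points with
    the optimistic (recall = 0, precision = 1) anchor replaced by a flat
    extension, so a constant predictor scores exactly the prevalence.  The
    per-regime table counts a true positive when the predicted Kd falls in the
    same affinity regime as the measured one.
    """
    if truth.kinases != predicted.kinases or truth.inhibitors != predicted.inhibitors:
        bad_k = sorted(set(truth.kinases) ^ set(predicted.kinases))
        bad_i = sorted(set(truth.inhibitors) ^ set(predicted.inhibitors))
        raise ValueError(
            "truth and prediction panels must share the kinase x inhibitor "
            f"index; mismatched kinases: {bad_k or 'order'}; inhibitors: {bad_i or 'order'}"
        )
    both = truth.measured & predicted.measured
    kd_t = truth.kd[both]
    kd_p = predicted.kd[both]
    cens = truth.censored[both]
    y_true = (kd_t <= binder_cutoff_nM) & ~cens
    if not y_true.any() or y_true.all():
        raise ValueError("ground truth must contain binders and non-binders")
    prec, rec, _ = precision_recall_curve(y_true.astype(int), -kd_p)
    # drop sklearn's appended (recall=0, precision=1) anchor, integrate the
    # threshold-ordered points (recall decreasing; equal-recall segments are
    # vertical and contribute nothing), then extend flat to recall 0
    prec, rec = prec[:-1], rec[:-1]
    aupr = float(-np.trapezoid(prec, rec) + rec[-1] * prec[-1])
    rows = []
    for name, lo, hi in regimes:
        in_true = (kd_t > lo) & (kd_t <= hi)
        in_pred = (kd_p > lo) & (kd_p <= hi)
        n_true = int(in_true.sum())
        tp = int((in_true & in_pred).sum())
        rows.append(
            {
                "regime": name,
                "n_true": n_true,
                "n_correct": tp,
                "tpr_percent": 100.0 * tp / n_true if n_true else np.nan,
            }
        )
    return PredictionEvaluation(
        precision=prec, recall=rec, aupr=aupr, regimes=pd.DataFrame(rows),
        binder_cutoff_nM=binder_cutoff_nM, prevalence=float(y_true.mean()),
    )


# ---------------------------------------------------------------------------
# Panel I/O

LONG_COLUMNS = ["kinase_id", "inhibitor_id", "dataset", "kd_nM", "censored"]


def panel_to_long(panel: BindingPanel, include_missing: bool = False) -> pd.DataFrame:
    """Long-form table; never-assayed pairs are skipped unless
    ``include_missing``, which writes them with an empty Kd (the serialized
    form then defines the full kinase x inhibitor grid and round-trips)."""
    rows = []
    for i, kin in enumerate(panel.kinases):
        for j, inh in enumerate(panel.inhibitors):
            if np.isnan(panel.kd[i, j]) and not include_missing:
                continue
            rows.append(
                (kin, inh, panel.datasets[j], panel.kd[i, j], bool(panel.censored[i, j]))
            )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def panel_from_long(df: pd.DataFrame, censor_value: float = DEFAULT_CENSOR_NM) -> BindingPanel:
    missing_cols = [c for c in LONG_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long-form panel lacks column(s): {', '.join(missing_cols)}")
    kinases = list(dict.fromkeys(df["kinase_id"]))
    inhibitors = list(dict.fromkeys(df["inhibitor_id"]))
    ds_map = dict(zip(df["inhibitor_id"], df["dataset"]))
    kd = np.full((len(kinases), len(inhibitors)), np.nan)
    cens = np.zeros(kd.shape, dtype=bool)
    ki = {k: i for i, k in enumerate(kinases)}
    ii = {h: j for j, h in enumerate(inhibitors)}
    has_flag = "censored" in df.columns
    for row in df.itertuples(index=False):
        i, j = ki[row.kinase_id], ii[row.inhibitor_id]
        kd[i, j] = float(row.kd_nM)
        if np.isnan(kd[i, j]):
            continue
        if has_flag:
            cens[i, j] = bool(row.censored)
        else:
            cens[i, j] = kd[i, j] >= censor_value
    return BindingPanel(
        kinases=kinases, inhibitors=inhibitors,
        datasets=[ds_map[h] for h in inhibitors],
        kd=kd, censored=cens, censor_value=censor_value,
    )


def write_panel_csv(panel: BindingPanel, path) -> None:
    panel_to_long(panel, include_missing=True).to_csv(path, index=False)


def read_panel_csv(path, censor_value: float = DEFAULT_CENSOR_NM) -> BindingPanel:
    return panel_from_long(pd.read_csv(path), censor_value)


def panel_from_wide(
    df: pd.DataFrame,
    datasets: dict[str, str] | str = "schrodinger",
    censor_value: float = DEFAULT_CENSOR_NM,
) -> BindingPanel:
    """Convert a wide table (kinase rows x inhibitor columns of Kd in nM).

    This is the layout of panel spreadsheets (one sheet per dataset);
    ``datasets`` maps inhibitor -> dataset tag, or a single tag for all.
    """
    kinases = [str(k) for k in df.index]
    inhibitors = [str(c) for c in df.columns]
    if isinstance(datasets, str):
        tags = [datasets] * len(inhibitors)
    else:
        tags = [datasets[h] for h in inhibitors]
    return BindingPanel(
        kinases=kinases, inhibitors=inhibitors, datasets=tags,
        kd=df.to_numpy(dtype=float), censor_value=censor_value,
    )


def read_panel_excel(
    path,
    sheet_datasets: dict[str, str],
    censor_value: float = DEFAULT_CENSOR_NM,
) -> BindingPanel:
    """Read a spreadsheet of wide-form sheets (kinase rows x inhibitor columns).

    ``sheet_datasets`` maps sheet name -> dataset tag; kinase ids are taken
    from the first column of each sheet and the sheets are joined on them.
    """
    frames = []
    for sheet, tag in sheet_datasets.items():
        df = pd.read_excel(path, sheet_name=sheet, index_col=0)
        frames.append(panel_to_long(panel_from_wide(df, tag, censor_value)))
    return panel_from_long(pd.concat(frames, ignore_index=True), censor_value)
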