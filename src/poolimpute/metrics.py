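"""Accuracy metrics for decoded and imputed genotypes.

Two complementary scores are used. Concordance is the fraction of
best-guess (argmax) genotypes equal to the truth, over all genotype
classes including homozygous reference. Cross-entropy,
``-ln p(true genotype)`` averaged over cells, distinguishes a confident
wrong call from a hesitant one: a prediction of (1, 0, 0) against truth
(0, 0, 1) is maximally penalized at ``-ln(eps)``, while (0.41, 0, 0.59)
against the same truth costs only ``-ln(0.59)``.

Markers are summarized per minor-allele-frequency (MAF) bin with edges
[0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50]; bins are half-open with the last
closed at 0.5. MAF is computed from the truth study population, not the
reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAF_EDGES = np.array([0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50])
N_BINS = len(MAF_EDGES) - 1
BIN_LABELS = [
    f"{MAF_EDGES[i]:.2f}-{MAF_EDGES[i + 1]:.2f}" for i in range(N_BINS)
]

DEFAULT_EPS = 1e-12


class MetricsError(ValueError):
    pass


def alternate_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-marker AAF over non-missing entries (missing sentinel = -1)."""
    d = np.asarray(dosages, dtype=float)
    valid = d >= 0
    with np.errstate(invalid="ignore"):
        return np.where(valid, d, 0.0).sum(axis=0) / (2.0 * valid.sum(axis=0))


def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    aaf = alternate_allele_frequency(dosages)
    return np.minimum(aaf, 1.0 - aaf)


def assign_maf_bins(maf: np.ndarray) -> np.ndarray:
    """Bin index 0..5 per marker; [lo, hi) bins, last closed at 0.50."""
    maf = np.asarray(maf, dtype=float)
    if (maf < 0).any() or (maf > 0.5 + 1e-12).any():
        raise MetricsError("MAF must lie in [0, 0.5]")
    idx = np.searchsorted(MAF_EDGES, maf, side="right") - 1
    return np.clip(idx, 0, N_BINS - 1)


def best_guess(posteriors: np.ndarray) -> np.ndarray:
    """Argmax dosage per cell; exact ties give -1 (never concordant)."""
    p = np.asarray(posteriors, dtype=float)
    g = p.argmax(axis=-1)
    top = p.max(axis=-1)
    ties = (np.isclose(p, top[..., None], rtol=0.0, atol=0.0)).sum(axis=-1) > 1
    return np.where(ties, -1, g)


def _per_bin(values_per_marker: np.ndarray, bins: np.ndarray) -> np.ndarray:
    out = np.full(N_BINS, np.nan)
    for b in range(N_BINS):
        sel = bins == b
        if sel.any():
            out[b] = float(values_per_marker[sel].mean())
    return out


def concordance(
    truth: np.ndarray,
    posteriors: np.ndarray,
    maf: np.ndarray | None = None,
    per_marker_mean: bool = True,
) -> dict:
    """Best-guess concordance, overall and per MAF bin.

    ``per_marker_mean`` averages the per-marker concordance over markers
    (each marker weighted equally); otherwise all cells are pooled.
    """
    truth = np.asarray(truth)
    if posteriors.shape[:2] != truth.shape:
        raise MetricsError(
            f"shape mismatch: truth {truth.shape} vs predicted {posteriors.shape[:2]}"
        )
    match = (best_guess(posteriors) == truth).astype(float)
    per_marker = match.mean(axis=0)
    overall = float(per_marker.mean()) if per_marker_mean else float(match.mean())
    res = {"overall": overall, "per_marker": per_marker}
    if maf is not None:
        res["per_bin"] = _per_bin(per_marker, assign_maf_bins(maf))
    return res


def cross_entropy(
    truth: np.ndarray,
    posteriors: np.ndarray,
    eps: float = DEFAULT_EPS,
    maf: np.ndarray | None = None,
    per_marker_mean: bool = True,
) -> dict:
    """Mean -ln p(true class), clipping probabilities below ``eps``.

    The clipped maximum ``-ln(eps)`` is attained when the true genotype
    receives (numerically) zero probability.
    """
    truth = np.asarray(truth)
    if not 0.0 < eps <= 1e-3:
        raise MetricsError("eps must lie in (0, 1e-3]")
    if posteriors.shape[:2] != truth.shape:
        raise MetricsError("shape mismatch between truth and predictions")
    p_true = np.take_along_axis(
        np.asarray(posteriors, dtype=float), truth[..., None].astype(int), axis=-1
    )[..., 0]
    ce = -np.log(np.maximum(p_true, eps))
    per_marker = ce.mean(axis=0)
    overall = float(per_marker.mean()) if per_marker_mean else float(ce.mean())
    res = {"overall": overall, "per_marker": per_marker}
    if maf is not None:
        res["per_bin"] = _per_bin(per_marker, assign_maf_bins(maf))
    return res


def decoded_fraction(
    decoded_simplexes: np.ndarray, maf: np.ndarray | None = None
) -> dict:
    """Fraction of fully decoded (one-hot) cells, overall and per bin."""
    p = np.asarray(decoded_simplexes)
    known = p.max(axis=-1) > 0.5 + 1e-9
    per_marker = known.mean(axis=0)
    res = {"overall": float(known.mean()), "per_marker": per_marker}
    if maf is not None:
        res["per_bin"] = _per_bin(per_marker, assign_maf_bins(maf))
    return res


def rolling_window_scores(
    scores: np.ndarray, mafs: np.ndarray, window: int = 5
) -> pd.DataFrame:
    """Per-marker scores smoothed in a centered window along ascending MAF.

    Markers are sorted by MAF; each score becomes the mean of the
    ``window``-marker centered window (2 previous + 2 next for window=5),
    truncated at the series ends. Quantile envelopes (0, 0.01, 0.25, 0.75,
    0.99, 1.0) are attached per 0.05-wide MAF bin for plotting.
    """
    scores = np.asarray(scores, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if window % 2 != 1:
        raise MetricsError("window must be odd")
    if len(scores) < window:
        raise MetricsError(f"need at least {window} markers, got {len(scores)}")
    order = np.argsort(mafs, kind="stable")
    df = pd.DataFrame({"maf": mafs[order], "score": scores[order]})
    df["smoothed"] = (
        df["score"].rolling(window, center=True, min_periods=1).mean()
    )
    df["maf_bin"] = np.minimum((df["maf"] // 0.05).astype(int), 9)
    qlevels = [0.0, 0.01, 0.25, 0.75, 0.99, 1.0]
    env = (
        df.groupby("maf_bin")["smoothed"]
        .quantile(qlevels)
        .unstack()
        .rename(columns={q: f"q{q:g}" for q in qlevels})
    )
    med = df.groupby("maf_bin")["smoothed"].median().rename("median")
    env = env.join(med)
    return df.join(env, on="maf_bin")


def aaf_heatmap(
    true_aaf: np.ndarray, sim_aaf: np.ndarray, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Joint AAF histogram, columns normalized per true-AAF bin.

    Returns ``(H, edges)`` where ``H[i, j]`` is the proportion of markers
    with simulated AAF in bin i among markers with true AAF in bin j. All
    mass on the diagonal means allele frequencies are perfectly preserved.
    """
    true_aaf = np.asarray(true_aaf, dtype=float)
    sim_aaf = np.asarray(sim_aaf, dtype=float)
    if true_aaf.size == 0:
        raise MetricsError("empty marker set")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    H, _, _ = np.histogram2d(sim_aaf, true_aaf, bins=(edges, edges))
    colsum = H.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(colsum > 0, H / colsum, 0.0)
    return H, edges


@dataclass
class MetricsReport:
    """Bundle of the standard evaluation outputs, JSON-serializable."""

    concordance_overall: float
    cross_entropy_overall: float
    concordance_per_bin: np.ndarray
    cross_entropy_per_bin: np.ndarray
    decoded_fraction_overall: float | None = None
    decoded_fraction_per_bin: np.ndarray | None = None
    bin_counts: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return [None if np.isnan(x) else float(x) for x in v]
            return v

        d = {
            "bin_labels": BIN_LABELS,
            "concordance_overall": self.concordance_overall,
            "cross_entropy_overall": self.cross_entropy_overall,
            "concordance_per_bin": conv(self.concordance_per_bin),
            "cross_entropy_per_bin": conv(self.cross_entropy_per_bin),
        }
        if self.decoded_fraction_overall is not None:
            d["decoded_fraction_overall"] = self.decoded_fraction_overall
            d["decoded_fraction_per_bin"] = conv(self.decoded_fraction_per_bin)
        if self.bin_counts is not None:
            d["bin_counts"] = [int(x) for x in self.bin_counts]
        d.update({k: conv(v) for k, v in self.extras.items()})
        return d


def evaluate(
    truth: np.ndarray,
    posteriors: np.ndarray,
    decoded_simplexes: np.ndarray | None = None,
    eps: float = DEFAULT_EPS,
) -> MetricsReport:
    """Full evaluation of predictions against a complete truth matrix."""
    maf = minor_allele_frequency(truth)
    bins = assign_maf_bins(maf)
    conc = concordance(truth, posteriors, maf=maf)
    ce = cross_entropy(truth, posteriors, eps=eps, maf=maf)
    rep = MetricsReport(
        concordance_overall=conc["overall"],
        cross_entropy_overall=ce["overall"],
        concordance_per_bin=conc["per_bin"],
        cross_entropy_per_bin=ce["per_bin"],
        bin_counts=np.bincount(bins, minlength=N_BINS),
    )
    if decoded_simplexes is not None:
        dec = decoded_fraction(decoded_simplexes, maf=maf)
        rep.decoded_fraction_overall = dec["overall"]
        rep.decoded_fraction_per_bin = dec["per_bin"]
    return rep
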