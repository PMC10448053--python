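"""Sloan neutral community model: fit, partition, and model comparison.

The model predicts a taxon's occupancy (fraction of samples where it is
detected) from its metacommunity mean relative abundance p via

    occupancy(p) = 1 - BetaCDF(d; N_T * m * p, N_T * m * (1 - p))

where N_T is the local community size (mean reads per sample), m the
immigration/migration parameter, and d the detection limit in relative
abundance units.  The single free parameter m is estimated by nonlinear
least squares of observed against predicted occupancy across taxa.

Taxa are partitioned by a 95% Wilson score band around the fitted curve:
inside = consistent with neutral assembly (stochastic), above/below =
deterministically over-/under-represented.  The stochastic:deterministic
ratio is the count inside the band over the count outside it.

A parameter-free binomial detection model (pure random sampling of the
source community) serves as the comparison model; AICs of both are
computed in the Gaussian-residual form AIC = n*ln(SS_res/n) + 2k with
k = 1 for the neutral fit and k = 0 for the binomial model, optionally
over bootstrap resamples of taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .tables_io import RelativeAbundanceView, ValidationError

M_BOUNDS = (1e-6, 1e3)
M_STARTS = (0.01, 0.1, 1.0)

#: Detection under multinomial read sampling at depth N is soft: a taxon at
#: latent fraction f appears with probability 1 - (1-f)^N, which crosses 1/2
#: at f = 1 - 2^(-1/N) ~ ln2/N.  Scaling the minimum observed fraction (1/N
#: after rarefaction) by ln2 makes the sharp-threshold occupancy model an
#: unbiased surrogate for that soft detection curve.
DETECTION_SCALE = float(np.log(2.0))


def _detection_limit(min_nonzero: float, mode: str) -> float:
    if mode == "effective":
        return DETECTION_SCALE * min_nonzero
    if mode == "min_observed":
        return min_nonzero
    raise ValueError(f"unknown detection-limit mode {mode!r}")


def predicted_occupancy(p, m: float, n_t: float, d: float):
    """Neutral-model occupancy for mean relative abundance(s) ``p``."""
    p = np.asarray(p, dtype=float)
    if m <= 0 or n_t <= 0:
        raise ValidationError("m and N_T must be positive")
    if not 0 < d < 1:
        raise ValidationError("detection limit d must be in (0, 1)")
    a = n_t * m * p
    b = n_t * m * (1.0 - p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("Beta shape parameters must be positive "
                              "(need 0 < p < 1)")
    return stats.beta.sf(d, a, b)


def binomial_occupancy(p, n_t: float, d: float):
    """Detection probability under pure multinomial sampling of the source.

    Probability that a taxon at source abundance p yields at least
    round(N_T * d) reads out of N_T draws.
    """
    p = np.asarray(p, dtype=float)
    n = int(round(n_t))
    k_min = max(int(round(n_t * d)), 1)
    return stats.binom.sf(k_min - 1, n, p)


@dataclass
class NeutralFitResult:
    m: float
    n_t: float
    d: float
    r_squared: float
    taxa: pd.DataFrame          # p, observed, predicted, lower95, upper95, partition
    counts: dict[str, int] = field(default_factory=dict)
    ratio: float = float("nan")
    aic_neutral: float = float("nan")
    aic_binomial: float = float("nan")
    ss_res_neutral: float = float("nan")
    ss_res_binomial: float = float("nan")

    def summary(self) -> dict:
        return {
            "m": self.m, "N_T": self.n_t, "d": self.d,
            "r_squared": self.r_squared,
            "aic_neutral": self.aic_neutral,
            "aic_binomial": self.aic_binomial,
            "n_neutral": self.counts.get("neutral", 0),
            "n_above": self.counts.get("above", 0),
            "n_below": self.counts.get("below", 0),
            "stochastic_deterministic_ratio": self.ratio,
        }


def _fit_m(p: np.ndarray, observed: np.ndarray, n_t: float, d: float) -> float:
    """Estimate m by bounded least squares with multiple starts."""
    def residuals(log_m):
        m = float(np.exp(np.asarray(log_m).ravel()[0]))
        return predicted_occupancy(p, m, n_t, d) - observed

    best = None
    lo, hi = np.log(M_BOUNDS[0]), np.log(M_BOUNDS[1])
    for start in M_STARTS:
        res = optimize.least_squares(residuals, x0=[np.log(start)],
                                     bounds=([lo], [hi]), xtol=1e-12,
                                     ftol=1e-12, gtol=1e-12)
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("neutral-model fit did not converge from any start")
    return float(np.exp(best.x[0]))


def gaussian_aic(ss_res: float, n: int, k: int) -> float:
    """AIC under iid Gaussian residuals: n*ln(SS/n) + 2k."""
    return n * np.log(ss_res / n) + 2 * k


def stochastic_deterministic_ratio(n_neutral: int, n_above: int,
                                   n_below: int) -> float:
    """Taxa inside the 95% band over taxa outside it."""
    outside = n_above + n_below
    if outside == 0:
        return float("inf")
    return n_neutral / outside


def wilson_band(predicted: np.ndarray, n_samples: int,
                alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """95% Wilson score interval around predicted occupancy, n = #samples."""
    lower, upper = proportion_confint(predicted * n_samples, n_samples,
                                      alpha=alpha, method="wilson")
    return np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def fit_neutral_model(view: RelativeAbundanceView,
                      n_t: float | None = None,
                      d: float | None = None,
                      detection_mode: str = "effective") -> NeutralFitResult:
    """Fit the neutral model to an abundance-occupancy distribution.

    Taxa with occupancy 0 are excluded (unobservable).  N_T defaults to
    the read-equivalent depth implied by the smallest nonzero fraction
    (the per-sample depth after rarefaction).  The detection limit d
    defaults to ln2 times the smallest observed nonzero relative
    abundance (``detection_mode="effective"``; see ``DETECTION_SCALE``);
    pass ``detection_mode="min_observed"`` for the raw minimum-fraction
    convention.
    """
    p = view.mean_abundance.to_numpy(dtype=float)
    occ = view.occupancy.to_numpy(dtype=float)
    keep = (p > 0) & (p < 1) & (occ > 0)
    taxa_ids = np.array(view.taxon_ids)[keep]
    p, occ = p[keep], occ[keep]
    if len(p) == 0 or np.all(occ >= 1):
        raise ValidationError("degenerate data: no taxa with occupancy in "
                              "(0, 1); cannot fit")
    informative = int(((occ > 0) & (occ < 1)).sum())
    if informative < 20:
        warnings.warn(f"only {informative} taxa with 0 < occupancy < 1; "
                      "fit may be unstable", stacklevel=2)
    fr = view.fractions.to_numpy(dtype=float)
    min_nonzero = float(fr[fr > 0].min())
    if n_t is None:
        n_t = 1.0 / min_nonzero
    if d is None:
        d = _detection_limit(min_nonzero, detection_mode)
    n_samples = view.n_samples

    m = _fit_m(p, occ, n_t, d)
    pred = predicted_occupancy(p, m, n_t, d)
    ss_res = float(((occ - pred) ** 2).sum())
    ss_tot = float(((occ - occ.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    lower, upper = wilson_band(pred, n_samples)
    partition = np.where(occ > upper, "above",
                         np.where(occ < lower, "below", "neutral"))
    counts = {lab: int((partition == lab).sum())
              for lab in ("neutral", "above", "below")}

    pred_binom = binomial_occupancy(p, n_t, d)
    ss_binom = float(((occ - pred_binom) ** 2).sum())
    n = len(p)

    taxa = pd.DataFrame({
        "p": p, "observed": occ, "predicted": pred,
        "lower95": lower, "upper95": upper, "partition": partition,
    }, index=taxa_ids)
    return NeutralFitResult(
        m=m, n_t=n_t, d=d, r_squared=r_squared, taxa=taxa, counts=counts,
        ratio=stochastic_deterministic_ratio(
            counts["neutral"], counts["above"], counts["below"]),
        aic_neutral=gaussian_aic(ss_res, n, k=1),
        aic_binomial=gaussian_aic(ss_binom, n, k=0),
        ss_res_neutral=ss_res, ss_res_binomial=ss_binom,
    )


def fit_binomial_model(view: RelativeAbundanceView,
                       n_t: float | None = None,
                       d: float | None = None,
                       detection_mode: str = "effective") -> tuple[np.ndarray, float]:
    """Parameter-free binomial detection model: predictions and SS_res."""
    p = view.mean_abundance.to_numpy(dtype=float)
    occ = view.occupancy.to_numpy(dtype=float)
    keep = (p > 0) & (occ > 0)
    p, occ = p[keep], occ[keep]
    fr = view.fractions.to_numpy(dtype=float)
    min_nonzero = float(fr[fr > 0].min())
    if n_t is None:
        n_t = 1.0 / min_nonzero
    if d is None:
        d = _detection_limit(min_nonzero, detection_mode)
    pred = binomial_occupancy(p, n_t, d)
    return pred, float(((occ - pred) ** 2).sum())


def bootstrap_aic(view: RelativeAbundanceView, n_boot: int = 1000,
                  seed: int = 0, detection_mode: str = "effective") -> dict:
    """Bootstrap (over taxa) AIC distributions for both models.

    Each replicate resamples taxa with replacement, refits m, and
    recomputes both AICs.  More than 10% failed refits is an error.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    p_all = view.mean_abundance.to_numpy(dtype=float)
    occ_all = view.occupancy.to_numpy(dtype=float)
    keep = (p_all > 0) & (p_all < 1) & (occ_all > 0)
    p_all, occ_all = p_all[keep], occ_all[keep]
    fr = view.fractions.to_numpy(dtype=float)
    min_nonzero = float(fr[fr > 0].min())
    n_t = 1.0 / min_nonzero
    d = _detection_limit(min_nonzero, detection_mode)
    n = len(p_all)
    rng = np.random.default_rng(seed)
    aic_n, aic_b = [], []
    failures = 0
    for rep in range(n_boot):
        idx = (np.arange(n) if n_boot == 1
               else rng.integers(0, n, size=n))
        p, occ = p_all[idx], occ_all[idx]
        try:
            m = _fit_m(p, occ, n_t, d)
        except RuntimeError:
            failures += 1
            continue
        ss_n = float(((occ - predicted_occupancy(p, m, n_t, d)) ** 2).sum())
        ss_b = float(((occ - binomial_occupancy(p, n_t, d)) ** 2).sum())
        aic_n.append(gaussian_aic(ss_n, n, 1))
        aic_b.append(gaussian_aic(ss_b, n, 0))
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    aic_n, aic_b = np.array(aic_n), np.array(aic_b)

    def ci(a):
        return [float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5))]

    return {
        "aic_neutral": aic_n, "aic_binomial": aic_b,
        "mean_aic_neutral": float(aic_n.mean()),
        "mean_aic_binomial": float(aic_b.mean()),
        "ci_aic_neutral": ci(aic_n), "ci_aic_binomial": ci(aic_b),
        "n_failures": failures,
    }
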