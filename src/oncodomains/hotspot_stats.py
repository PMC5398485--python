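"""Zero-inflated-Poisson empirical null, local FDR, and hotspot calling.

Per (domain family, cancer type) the per-position mutation counts j are
modeled as a two-component mixture

    f(j) = p0 * f0(j) + p1 * f1(j)

where the null f0 is Zero-Inflated Poisson — a point mass pi at zero mixed
with Poisson(lam0) — and the non-null f1 is Poisson(lam1) with the
identifiability constraint lam1 >= lam0.  The local false discovery rate at
count t,

    fdr(t) = p0 * f0(t) / f(t),

is the posterior probability that a position carrying t variants is
non-significant.  Positions with count >= 1 and fdr below the cutoff
(default 0.05) are called oncodomain hotspots; a family with at least one
hotspot is an oncodomain.

Each family is fit separately: aligned positions of one family share their
genomic covariates (replication timing, expression, chromatin state), so no
covariate model is needed.  The estimator is an EM on the count histogram
n_j; the fdr denominator uses the fitted mixture rather than the raw
histogram for stability on short domains, and fdr is monotonized over t >= 1
by a cumulative minimum so calls are nested in t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .domain_mapping import PositionCounts

__all__ = [
    "FitConfig",
    "MixtureFit",
    "HotspotCall",
    "OncodomainSummary",
    "zip_pmf",
    "zip_logpmf",
    "fit_null_mixture",
    "local_fdr",
    "local_fdr_table",
    "tail_fdr_table",
    "call_hotspots",
    "summarize",
    "simulate_random_background",
]


def zip_logpmf(j, pi_zero: float, lam0: float):
    """Log-pmf of the Zero-Inflated Poisson: log[pi*1{j=0} + (1-pi)*Pois(j;lam)].

    Vectorized over j; computed in log space so large counts do not underflow.
    """
    if not 0.0 <= pi_zero <= 1.0:
        raise ValueError(f"pi_zero must be in [0, 1], got {pi_zero}")
    if lam0 < 0:
        raise ValueError(f"lam0 must be >= 0, got {lam0}")
    j = np.asarray(j)
    with np.errstate(divide="ignore"):
        lp = np.where(
            lam0 > 0, poisson.logpmf(j, max(lam0, 1e-300)), np.where(j == 0, 0.0, -np.inf)
        )
        lp = lp + math.log1p(-pi_zero) if pi_zero < 1.0 else np.full_like(lp, -np.inf)
        out = np.where(
            j == 0,
            np.logaddexp(math.log(pi_zero) if pi_zero > 0 else -np.inf, lp),
            lp,
        )
    return out


def zip_pmf(j, pi_zero: float, lam0: float):
    """ZIP pmf: f0(0) = pi + (1-pi) e^{-lam}; f0(j) = (1-pi) e^{-lam} lam^j / j!."""
    return np.exp(zip_logpmf(j, pi_zero, lam0))


@dataclass(frozen=True)
class FitConfig:
    max_iter: int = 500
    tol: float = 1e-8
    min_positions: int = 10
    support_cap: int | None = None  # default: max(j_max, lam1 + 10*sqrt(lam1))


@dataclass
class MixtureFit:
    """Fitted two-component mixture p0*ZIP(pi_zero, lam0) + p1*Poisson(lam1)."""

    pi_zero: float
    lam0: float
    p0: float
    lam1: float
    loglik: float
    converged: bool
    n_iter: int
    degenerate: bool = False
    support: np.ndarray = field(default_factory=lambda: np.arange(1))

    @property
    def p1(self) -> float:
        return 1.0 - self.p0

    def f0_of(self, j):
        return zip_pmf(j, self.pi_zero, self.lam0)

    def f1_of(self, j):
        return poisson.pmf(j, self.lam1) if self.lam1 > 0 else (np.asarray(j) == 0) * 1.0

    def f_of(self, j):
        return self.p0 * self.f0_of(j) + self.p1 * self.f1_of(j)


def _histogram_arrays(histogram: Mapping[int, int]) -> tuple[np.ndarray, np.ndarray]:
    js = np.array(sorted(histogram), dtype=int)
    ns = np.array([histogram[j] for j in js], dtype=float)
    if (js < 0).any() or (ns < 0).any():
        raise ValueError("histogram must map non-negative counts to non-negative n_j")
    return js, ns


def _initial_params(js: np.ndarray, ns: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-based starting point: lam0 from the mean of counts at or below
    the median nonzero count, pi from excess zeros over that Poisson, p0=0.95,
    lam1 from the top decile."""
    n_total = ns.sum()
    nonzero = js[js > 0]
    if nonzero.size == 0:
        return 0.9, 0.0, 1.0, 0.0
    med_nz = float(np.median(np.repeat(nonzero, ns[js > 0].astype(int))))
    low = js <= med_nz
    lam0 = float((js[low] * ns[low]).sum() / ns[low].sum())
    lam0 = max(lam0, 1e-3)
    zero_frac = float(ns[js == 0].sum() / n_total) if (js == 0).any() else 0.0
    e = math.exp(-lam0)
    pi = (zero_frac - e) / (1.0 - e) if e < 1.0 else 0.0
    # pi = 0 is an absorbing fixed point of the EM (a structural-zero
    # responsibility of zero can never become positive), so start strictly
    # inside the parameter space
    pi = min(max(pi, 0.05), 0.95)
    expanded = np.repeat(js, ns.astype(int))
    q90 = np.quantile(expanded, 0.9)
    top = expanded[expanded >= q90]
    lam1 = max(2.0 * lam0, float(top.mean()) if top.size else 2.0 * lam0)
    return pi, lam0, 0.95, lam1


def _fit_zip_only(
    js: np.ndarray, ns: np.ndarray, pi: float, lam: float, config: FitConfig
) -> tuple[float, float, float, bool, int]:
    """EM for a pure ZIP on the histogram (used when the mixture degrades to
    the null)."""
    n_total = ns.sum()
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        lp = zip_logpmf(js, pi, lam)
        ll = float((ns * lp).sum())
        if ll_prev != -np.inf and abs(ll - ll_prev) <= config.tol * abs(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        # E: posterior that an observed zero is a structural zero
        if pi > 0 and (js == 0).any():
            denom = pi + (1 - pi) * math.exp(-lam)
            z0 = ns[js == 0][0] * (pi / denom)
        else:
            z0 = 0.0
        pi = z0 / n_total
        denom_n = n_total - z0
        lam = float((js * ns).sum() / denom_n) if denom_n > 0 else 0.0
        pi = min(max(pi, 0.0), 1.0)
    return pi, lam, ll_prev, converged, it


def fit_null_mixture(
    histogram: Mapping[int, int] | PositionCounts,
    config: FitConfig = FitConfig(),
) -> MixtureFit | None:
    """EM fit of p0*ZIP(pi, lam0) + p1*Poisson(lam1) to a count histogram.

    Returns None (skip signal) when the family has fewer than
    ``config.min_positions`` positions.  All-zero counts yield a degenerate
    pure-null fit.  If the fitted non-null weight p1 falls below one expected
    position (1/N), the fit degrades gracefully to a pure null refit.
    The log-likelihood is checked to be non-decreasing at every iteration.
    """
    if isinstance(histogram, PositionCounts):
        histogram = histogram.histogram
    js, ns = _histogram_arrays(histogram)
    n_total = ns.sum()
    if n_total < config.min_positions:
        return None
    if (js[ns > 0] == 0).all():
        fit = MixtureFit(
            pi_zero=1.0, lam0=0.0, p0=1.0, lam1=0.0,
            loglik=0.0, converged=True, n_iter=0, degenerate=True,
        )
        fit.support = np.arange(1)
        return fit

    pi, lam0, p0, lam1 = _initial_params(js, ns)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        log_f0 = zip_logpmf(js, pi, lam0)
        log_f1 = poisson.logpmf(js, max(lam1, 1e-300))
        with np.errstate(divide="ignore"):
            a = math.log(p0) + log_f0 if p0 > 0 else np.full_like(log_f0, -np.inf)
            b = math.log1p(-p0) + log_f1 if p0 < 1 else np.full_like(log_f1, -np.inf)
        log_f = np.logaddexp(a, b)
        ll = float((ns * log_f).sum())
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_prev} -> {ll} at iteration {it}"
            )
        if ll_prev != -np.inf and abs(ll - ll_prev) <= config.tol * abs(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        # E-step
        g1 = np.exp(b - log_f)  # responsibility of the non-null component
        g0 = 1.0 - g1
        w0 = ns * g0
        w1 = ns * g1
        # M-step
        s1 = w1.sum()
        p0 = 1.0 - s1 / n_total
        if s1 > 0:
            lam1 = float((js * w1).sum() / s1)
        zero_mask = js == 0
        if pi > 0 and zero_mask.any():
            denom = pi + (1 - pi) * math.exp(-lam0)
            z0 = float(w0[zero_mask].sum() * (pi / denom))
        else:
            z0 = 0.0
        s0 = w0.sum()
        pi = z0 / s0 if s0 > 0 else 0.0
        pi = min(max(pi, 0.0), 1.0)
        denom0 = s0 - z0
        lam0 = float((js * w0).sum() / denom0) if denom0 > 0 else 0.0
        if lam1 < lam0:
            lam1 = lam0
        p0 = min(max(p0, 0.0), 1.0)

    # Degrade to a pure null when the non-null component earns less than one
    # expected position, or when it does not pay for its two extra parameters
    # (BIC): on homogeneous null data the two components would otherwise
    # split the null between them and deflate p0.
    pi_n, lam_n, _, _ = _initial_params(js, ns)
    pi0, lam00, ll_null, conv_null, it_null = _fit_zip_only(js, ns, pi_n, lam_n, config)
    if (1.0 - p0) < 1.0 / n_total or 2.0 * (ll_prev - ll_null) <= 2.0 * math.log(n_total):
        pi, lam0, lam1 = pi0, lam00, lam00
        p0, ll_prev, converged = 1.0, ll_null, conv_null
        it += it_null

    cap = config.support_cap
    if cap is None:
        cap = int(max(js.max(), math.ceil(lam1 + 10.0 * math.sqrt(max(lam1, 1.0)))))
    fit = MixtureFit(
        pi_zero=pi, lam0=lam0, p0=p0, lam1=lam1,
        loglik=ll_prev, converged=converged, n_iter=it,
    )
    fit.support = np.arange(cap + 1)
    return fit


def local_fdr_table(fit: MixtureFit, t_max: int | None = None) -> np.ndarray:
    """fdr(t) = min(1, p0 f0(t) / f(t)) for t = 0..t_max, with a cumulative
    minimum applied over t >= 1 so the values are non-increasing in t.

    Underflow of f(t) is resolved in favor of whichever component's density
    dominates: fdr is 0 if f0 underflows faster than f1, else 1; never NaN.
    """
    if t_max is None:
        t_max = int(fit.support.max())
    t = np.arange(t_max + 1)
    log_f0 = zip_logpmf(t, fit.pi_zero, fit.lam0)
    if fit.lam1 > 0:
        log_f1 = poisson.logpmf(t, fit.lam1)
    else:
        log_f1 = np.where(t == 0, 0.0, -np.inf)
    with np.errstate(divide="ignore"):
        a = (math.log(fit.p0) if fit.p0 > 0 else -np.inf) + log_f0
        b = (math.log1p(-fit.p0) if fit.p0 < 1 else -np.inf) + log_f1
    log_f = np.logaddexp(a, b)
    with np.errstate(invalid="ignore"):
        raw = np.exp(a - log_f)
    # underflow tie-break: both components' mass vanished at this t
    dead = ~np.isfinite(log_f)
    if dead.any():
        raw[dead] = np.where(log_f0[dead] >= log_f1[dead], 1.0, 0.0)
    raw = np.minimum(raw, 1.0)
    out = raw.copy()
    if t_max >= 1:
        out[1:] = np.minimum.accumulate(raw[1:])
    return out


def local_fdr(t: int, fit: MixtureFit) -> float:
    """Monotonized local FDR at a single count level t."""
    table = local_fdr_table(fit, t_max=max(t, int(fit.support.max())))
    return float(table[t])


def tail_fdr_table(fit: MixtureFit, t_max: int | None = None) -> np.ndarray:
    """Tail-area FDR (q-value analogue): Fdr(t) = p0 P0(J>=t) / P(J>=t)."""
    if t_max is None:
        t_max = int(fit.support.max())
    grid = np.arange(max(t_max, int(fit.support.max())) + 1)
    f0 = fit.f0_of(grid)
    f = fit.f_of(grid)
    s0 = np.minimum(f0[::-1].cumsum()[::-1], 1.0)
    s = np.minimum(f[::-1].cumsum()[::-1], 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0, fit.p0 * s0 / s, 1.0)
    return np.minimum(out, 1.0)[: t_max + 1]


@dataclass(frozen=True)
class HotspotCall:
    domain_acc: str
    cancer_type: str
    model_pos: int
    count: int
    fdr_local: float
    fdr_tail: float
    significant: bool


def call_hotspots(
    counts: PositionCounts,
    fit: MixtureFit,
    cutoff: float = 0.05,
    include_all: bool = False,
) -> list[HotspotCall]:
    """Call hotspot positions: count >= 1 and local fdr < cutoff.

    Zero-count positions are never significant.  With ``include_all`` every
    nonzero position is returned with its fdr (significant flag set as
    appropriate); otherwise only significant positions are returned.
    """
    t_max = int(counts.counts.max(initial=0))
    fdr = local_fdr_table(fit, t_max=t_max)
    qtab = tail_fdr_table(fit, t_max=t_max)
    calls = []
    for pos0 in np.flatnonzero(counts.counts > 0):
        t = int(counts.counts[pos0])
        sig = fdr[t] < cutoff
        if sig or include_all:
            calls.append(
                HotspotCall(
                    domain_acc=counts.domain_acc,
                    cancer_type=counts.cancer_type,
                    model_pos=int(pos0) + 1,
                    count=t,
                    fdr_local=float(fdr[t]),
                    fdr_tail=float(qtab[t]),
                    significant=bool(sig),
                )
            )
    return calls


@dataclass
class OncodomainSummary:
    cancer_type: str
    n_oncodomains: dict[float, int]
    n_hotspots: dict[float, int]
    hotspot_positions: dict[str, list[int]]


def summarize(
    calls: Sequence[HotspotCall], cutoffs: Sequence[float] = (0.05, 0.01)
) -> list[OncodomainSummary]:
    """Per-cancer-type roll-up: number of oncodomains (families with >= 1
    significant position) and hotspots at each cutoff."""
    by_ct: dict[str, list[HotspotCall]] = {}
    for c in calls:
        by_ct.setdefault(c.cancer_type, []).append(c)
    out = []
    for ct in sorted(by_ct):
        group = by_ct[ct]
        n_onco = {}
        n_hot = {}
        for cut in cutoffs:
            sig = [c for c in group if c.count >= 1 and c.fdr_local < cut]
            n_onco[cut] = len({c.domain_acc for c in sig})
            n_hot[cut] = len(sig)
        primary = min(cutoffs) if cutoffs else 0.05
        positions: dict[str, list[int]] = {}
        for c in group:
            if c.fdr_local < max(cutoffs):
                positions.setdefault(c.domain_acc, []).append(c.model_pos)
        out.append(
            OncodomainSummary(
                cancer_type=ct,
                n_oncodomains=n_onco,
                n_hotspots=n_hot,
                hotspot_positions={k: sorted(v) for k, v in sorted(positions.items())},
            )
        )
    return out


def summary_frame(summaries: Sequence[OncodomainSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"cancer_type": s.cancer_type}
        for cut in sorted(s.n_oncodomains, reverse=True):
            row[f"n_oncodomains_{cut}"] = s.n_oncodomains[cut]
            row[f"n_hotspots_{cut}"] = s.n_hotspots[cut]
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_random_background(
    n_variants: int, model_length: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Diagnostic null: n_variants placed uniformly at random over the model
    positions (multinomial), mirroring a randomly distributed background of
    the same size as the observed nonsynonymous variants."""
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    return rng.multinomial(n_variants, np.full(model_length, 1.0 / model_length))
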