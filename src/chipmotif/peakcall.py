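"""Binding-event detection from directional reads.

The model: within a candidate region, forward-read 5' positions follow a
mixture sum_k w_k t_nu(mu_k - delta_k/2, sigma_fk^2) and reverse-read 5'
positions follow sum_k w_k t_nu(mu_k + delta_k/2, sigma_rk^2), sharing the
component weights. mu_k is the binding-site position and delta_k the
forward/reverse mode separation (~ mean fragment length). Priors:
delta_k ~ Normal(xi, delta_sd^2) and sigma^2 ~ InvGamma(a, b), so closely
spaced events with few reads borrow strength from the expected fragment size.
Estimation is MAP-EM via the normal/gamma scale-mixture representation of the
t distribution; a step-halving safeguard guarantees a non-decreasing penalized
log-likelihood on every iteration, including truncated (mappability-corrected)
fits where the M-step is not closed form.

Mappability correction: each component density is renormalized over the
mappable subset of the region, with the normalizer computed as
Z = 1 - sum over non-mappable 1-bp grid positions of the component pdf, so a
profile with no gaps reduces exactly to the uncorrected model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import invgamma, norm
from scipy.stats import t as t_dist

from .core_io import AlignedRead, GenomicInterval, MappabilityProfile


@dataclass
class PeakPriors:
    """Hyperparameters of the binding-event model.

    xi is the prior mean fragment length (bp); delta_sd its prior sd; a, b the
    inverse-gamma shape/scale for the read-spread variance; nu the t degrees
    of freedom (heavy-tailed but finite-variance).
    """

    xi: float = 175.0
    delta_sd: float = 50.0
    a: float = 2.0
    b: float = 2.0 * 35.0**2
    nu: float = 4.0

    def __post_init__(self):
        if self.xi <= 0 or self.delta_sd <= 0 or self.a <= 1 or self.nu <= 2:
            raise ValueError("require xi > 0, delta_sd > 0, a > 1, nu > 2")


@dataclass
class PeakConfig:
    window: int = 300
    step: int = 50
    min_fwd: int = 5
    min_rev: int = 5
    Kmax: int = 3
    tol: float = 1e-6
    max_iter: int = 500
    eps: float = 0.5           # floor on the scaled local control count
    top: int | None = None


@dataclass
class CandidateRegion:
    interval: GenomicInterval
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self):
        self.fwd = np.sort(np.asarray(self.fwd, dtype=float))
        self.rev = np.sort(np.asarray(self.rev, dtype=float))

    @property
    def n_reads(self) -> int:
        return len(self.fwd) + len(self.rev)


@dataclass
class EventComponent:
    mu: float
    delta: float
    sigma_f: float
    sigma_r: float
    weight: float
    mu_se: float = np.nan


@dataclass
class MixtureFit:
    K: int
    components: list[EventComponent]
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    pruned: bool = False
    merged: bool = False
    degenerate_fallback: bool = False


@dataclass
class BindingEvent:
    chrom: str
    mu: float
    delta: float
    score: float
    ci_lo: float
    ci_hi: float
    n_frag_est: float
    sigma_f: float = np.nan
    sigma_r: float = np.nan
    fdr: float = np.nan


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_regions(reads: Sequence[AlignedRead], priors: PeakPriors | None = None,
                    min_fwd: int = 5, min_rev: int = 5,
                    window: int = 300, step: int = 50) -> list[CandidateRegion]:
    """Sliding-window segmentation into candidate binding regions.

    Windows with at least min_fwd forward and min_rev reverse 5' positions are
    kept; overlapping kept windows are merged and each merged region extended
    by xi on both sides. Reads are assigned to the region containing their
    pos5.
    """
    priors = priors or PeakPriors()
    xi = int(round(priors.xi))
    by_chrom: dict[str, tuple[list[float], list[float]]] = {}
    for r in reads:
        fwd, rev = by_chrom.setdefault(r.chrom, ([], []))
        (fwd if r.strand == "+" else rev).append(float(r.pos5))
    regions: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        fwd = np.sort(np.asarray(by_chrom[chrom][0]))
        rev = np.sort(np.asarray(by_chrom[chrom][1]))
        if len(fwd) < min_fwd or len(rev) < min_rev:
            continue
        lo = int(min(fwd[0], rev[0]) // step * step) - window
        hi = int(max(fwd[-1], rev[-1]))
        starts = np.arange(lo, hi + step, step)
        nf = np.searchsorted(fwd, starts + window, side="left") - np.searchsorted(fwd, starts, side="left")
        nr = np.searchsorted(rev, starts + window, side="left") - np.searchsorted(rev, starts, side="left")
        keep = (nf >= min_fwd) & (nr >= min_rev)
        if not keep.any():
            continue
        merged: list[list[int]] = []
        for s in starts[keep]:
            s, e = int(s), int(s) + window
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        # extend by xi, then re-merge extensions that collide
        extended: list[list[int]] = []
        for s, e in merged:
            s, e = max(0, s - xi), e + xi
            if extended and s <= extended[-1][1]:
                extended[-1][1] = max(extended[-1][1], e)
            else:
                extended.append([s, e])
        for s, e in extended:
            f = fwd[(fwd >= s) & (fwd < e)]
            r = rev[(rev >= s) & (rev < e)]
            if len(f) == 0 or len(r) == 0:
                continue
            regions.append(CandidateRegion(GenomicInterval(chrom, s, e), f, r))
    return regions


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

class _Params:
    __slots__ = ("mu", "delta", "sf", "sr", "w")

    def __init__(self, mu, delta, sf, sr, w):
        self.mu, self.delta, self.sf, self.sr, self.w = (
            np.asarray(mu, float), np.asarray(delta, float),
            np.asarray(sf, float), np.asarray(sr, float), np.asarray(w, float))

    def blend(self, other: "_Params", frac: float) -> "_Params":
        return _Params(*(a + frac * (b - a) for a, b in zip(
            (self.mu, self.delta, self.sf, self.sr, self.w),
            (other.mu, other.delta, other.sf, other.sr, other.w))))


def _gap_grid(region: CandidateRegion, map_profile: MappabilityProfile | None) -> np.ndarray:
    if map_profile is None:
        return np.empty(0)
    gaps = map_profile.gaps_within(region.interval.chrom, region.interval.start,
                                   region.interval.end)
    if len(gaps) == 0:
        return np.empty(0)
    return np.concatenate([np.arange(s, e, dtype=float) + 0.5 for s, e in gaps])


def _log_trunc_norm(centers: np.ndarray, sigmas: np.ndarray, nu: float,
                    gap_grid: np.ndarray) -> np.ndarray:
    """log Z_k where Z = 1 - sum_{gap grid} t_pdf; zeros when no gaps."""
    if len(gap_grid) == 0:
        return np.zeros(len(centers))
    pdf = t_dist.pdf((gap_grid[None, :] - centers[:, None]) / sigmas[:, None], df=nu)
    mass = (pdf / sigmas[:, None]).sum(axis=1)
    return np.log(np.clip(1.0 - mass, 1e-12, 1.0))


def _strand_loglik(x: np.ndarray, centers: np.ndarray, sigmas: np.ndarray,
                   nu: float, log_z: np.ndarray) -> np.ndarray:
    """(n, K) per-read per-component truncated t log-density."""
    z = (x[:, None] - centers[None, :]) / sigmas[None, :]
    return t_dist.logpdf(z, df=nu) - np.log(sigmas)[None, :] - log_z[None, :]


def _penalized_loglik(params: _Params, xf, xr, priors: PeakPriors,
                      gap_grid: np.ndarray) -> float:
    cf = params.mu - params.delta / 2.0
    cr = params.mu + params.delta / 2.0
    lzf = _log_trunc_norm(cf, params.sf, priors.nu, gap_grid)
    lzr = _log_trunc_norm(cr, params.sr, priors.nu, gap_grid)
    lw = np.log(np.clip(params.w, 1e-300, None))
    ll = logsumexp(lw[None, :] + _strand_loglik(xf, cf, params.sf, priors.nu, lzf), axis=1).sum()
    ll += logsumexp(lw[None, :] + _strand_loglik(xr, cr, params.sr, priors.nu, lzr), axis=1).sum()
    prior = norm.logpdf(params.delta, priors.xi, priors.delta_sd).sum()
    prior += invgamma.logpdf(params.sf**2, priors.a, scale=priors.b).sum()
    prior += invgamma.logpdf(params.sr**2, priors.a, scale=priors.b).sum()
    return float(ll + prior)


def _init_params(xf: np.ndarray, xr: np.ndarray, K: int, priors: PeakPriors) -> _Params:
    implied = np.sort(np.concatenate([xf + priors.xi / 2.0, xr - priors.xi / 2.0]))
    qs = (np.arange(K) + 0.5) / K
    mu = np.quantile(implied, qs)
    for _ in range(8):  # 1-D Lloyd refinement, deterministic
        assign = np.argmin(np.abs(implied[:, None] - mu[None, :]), axis=1)
        for k in range(K):
            pts = implied[assign == k]
            if len(pts):
                mu[k] = pts.mean()
    mu = np.sort(mu)
    assign = np.argmin(np.abs(implied[:, None] - mu[None, :]), axis=1)
    w = np.array([max((assign == k).mean(), 0.05) for k in range(K)])
    w /= w.sum()
    sig = np.array([max(np.std(implied[assign == k]), 25.0) if (assign == k).any() else 50.0
                    for k in range(K)])
    sig = np.clip(sig, 25.0, 200.0)
    return _Params(mu, np.full(K, priors.xi), sig, sig.copy(), w)


def _ghost_stats(center: float, sigma: float, nu: float, z_sum: float,
                 gap_grid: np.ndarray):
    """Expected sufficient statistics of reads lost to non-mappable gaps.

    Truncated-data EM by augmentation: per observed responsibility mass z_sum,
    the expected number of unobserved reads in the gaps is z_sum * m / (1 - m)
    where m is the component mass inside the gaps; their positions follow the
    component density restricted to the gaps (evaluated on the 1-bp grid).
    Returns (weights, u_weights, positions) of the imputed grid points.
    """
    if len(gap_grid) == 0:
        return None
    t2 = ((gap_grid - center) / sigma) ** 2
    pdf = t_dist.pdf(np.sqrt(t2) * np.sign(gap_grid - center), df=nu) / sigma
    m = float(pdf.sum())
    if m < 1e-12:
        return None
    m = min(m, 0.999)
    ghost_w = z_sum * pdf / (1.0 - m)
    u = (nu + 1.0) / (nu + t2)
    return ghost_w, u, gap_grid


def _em_step(params: _Params, xf, xr, priors: PeakPriors, gap_grid: np.ndarray) -> _Params:
    nu = priors.nu
    cf = params.mu - params.delta / 2.0
    cr = params.mu + params.delta / 2.0
    lzf = _log_trunc_norm(cf, params.sf, nu, gap_grid)
    lzr = _log_trunc_norm(cr, params.sr, nu, gap_grid)
    lw = np.log(np.clip(params.w, 1e-300, None))
    lf = lw[None, :] + _strand_loglik(xf, cf, params.sf, nu, lzf)
    lr = lw[None, :] + _strand_loglik(xr, cr, params.sr, nu, lzr)
    zf = np.exp(lf - logsumexp(lf, axis=1, keepdims=True))
    zr = np.exp(lr - logsumexp(lr, axis=1, keepdims=True))
    uf = (nu + 1.0) / (nu + ((xf[:, None] - cf[None, :]) / params.sf[None, :]) ** 2)
    ur = (nu + 1.0) / (nu + ((xr[:, None] - cr[None, :]) / params.sr[None, :]) ** 2)

    K = len(params.mu)
    w_new = (zf.sum(axis=0) + zr.sum(axis=0)) / (len(xf) + len(xr))
    mu_new = params.mu.copy()
    delta_new = params.delta.copy()
    sf_new = params.sf.copy()
    sr_new = params.sr.copy()
    for k in range(K):
        wf = zf[:, k] * uf[:, k]
        wr = zr[:, k] * ur[:, k]
        gf = _ghost_stats(cf[k], params.sf[k], nu, zf[:, k].sum(), gap_grid)
        gr = _ghost_stats(cr[k], params.sr[k], nu, zr[:, k].sum(), gap_grid)
        Sf, Sxf, Nf = wf.sum(), float(np.dot(wf, xf)), zf[:, k].sum()
        Sr, Sxr, Nr = wr.sum(), float(np.dot(wr, xr)), zr[:, k].sum()
        if gf is not None:
            gw, gu, gx = gf
            Sf += float(np.dot(gw, gu))
            Sxf += float(np.dot(gw * gu, gx))
            Nf += float(gw.sum())
        if gr is not None:
            gw, gu, gx = gr
            Sr += float(np.dot(gw, gu))
            Sxr += float(np.dot(gw * gu, gx))
            Nr += float(gw.sum())
        if Sf < 1e-12 or Sr < 1e-12:
            continue
        xbf = Sxf / Sf
        xbr = Sxr / Sr
        A = Sf / params.sf[k] ** 2
        B = Sr / params.sr[k] ** 2
        P = 1.0 / priors.delta_sd**2
        # solve for (mu, delta): stationarity of the penalized Q-function
        M = np.array([[A + B, -(A - B) / 2.0],
                      [-(A - B) / 2.0, (A + B) / 4.0 + P]])
        v = np.array([A * xbf + B * xbr,
                      -(A * xbf - B * xbr) / 2.0 + priors.xi * P])
        try:
            mu_k, delta_k = np.linalg.solve(M, v)
        except np.linalg.LinAlgError:
            continue
        mu_new[k] = mu_k
        delta_new[k] = max(delta_k, 1.0)
        cfk = mu_new[k] - delta_new[k] / 2.0
        crk = mu_new[k] + delta_new[k] / 2.0
        ssf = float(np.dot(wf, (xf - cfk) ** 2))
        ssr = float(np.dot(wr, (xr - crk) ** 2))
        if gf is not None:
            gw, gu, gx = gf
            ssf += float(np.dot(gw * gu, (gx - cfk) ** 2))
        if gr is not None:
            gw, gu, gx = gr
            ssr += float(np.dot(gw * gu, (gx - crk) ** 2))
        sf_new[k] = np.sqrt((2.0 * priors.b + ssf) / (2.0 * (priors.a + 1.0) + Nf))
        sr_new[k] = np.sqrt((2.0 * priors.b + ssr) / (2.0 * (priors.a + 1.0) + Nr))
    sf_new = np.clip(sf_new, 1.0, None)
    sr_new = np.clip(sr_new, 1.0, None)
    w_new = np.clip(w_new, 1e-8, None)
    w_new /= w_new.sum()
    return _Params(mu_new, delta_new, sf_new, sr_new, w_new)


def _mu_standard_errors(params: _Params, xf, xr, priors: PeakPriors,
                        gap_grid: np.ndarray) -> np.ndarray:
    """Observed-information (scale-mixture) approximation of se(mu_k)."""
    nu = priors.nu
    cf = params.mu - params.delta / 2.0
    cr = params.mu + params.delta / 2.0
    lzf = _log_trunc_norm(cf, params.sf, nu, gap_grid)
    lzr = _log_trunc_norm(cr, params.sr, nu, gap_grid)
    lw = np.log(np.clip(params.w, 1e-300, None))
    lf = lw[None, :] + _strand_loglik(xf, cf, params.sf, nu, lzf)
    lr = lw[None, :] + _strand_loglik(xr, cr, params.sr, nu, lzr)
    zf = np.exp(lf - logsumexp(lf, axis=1, keepdims=True))
    zr = np.exp(lr - logsumexp(lr, axis=1, keepdims=True))
    uf = (nu + 1.0) / (nu + ((xf[:, None] - cf[None, :]) / params.sf[None, :]) ** 2)
    ur = (nu + 1.0) / (nu + ((xr[:, None] - cr[None, :]) / params.sr[None, :]) ** 2)
    info = (zf * uf / params.sf[None, :] ** 2).sum(axis=0) + \
           (zr * ur / params.sr[None, :] ** 2).sum(axis=0)
    return 1.0 / np.sqrt(np.clip(info, 1e-12, None))


def fit_mixture(region: CandidateRegion, K: int, priors: PeakPriors | None = None,
                map_profile: MappabilityProfile | None = None,
                tol: float = 1e-6, max_iter: int = 500) -> MixtureFit:
    """MAP-EM fit of a K-component directional t-mixture to one region."""
    priors = priors or PeakPriors()
    if K < 1:
        raise ValueError("K must be >= 1")
    xf, xr = region.fwd, region.rev
    if len(xf) < 2 or len(xr) < 2:
        raise ValueError("need >= 2 reads per strand")
    gap_grid = _gap_grid(region, map_profile)
    params = _init_params(xf, xr, K, priors)
    ll = _penalized_loglik(params, xf, xr, priors, gap_grid)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        proposal = _em_step(params, xf, xr, priors, gap_grid)
        ll_new = _penalized_loglik(proposal, xf, xr, priors, gap_grid)
        if not np.isfinite(ll_new) or ll_new < ll - 1e-10 * (1.0 + abs(ll)):
            # step-halving safeguard (needed when truncation makes the
            # M-step inexact); guarantees a non-decreasing trace
            frac, accepted = 0.5, False
            for _ in range(40):
                cand = params.blend(proposal, frac)
                ll_c = _penalized_loglik(cand, xf, xr, priors, gap_grid)
                if np.isfinite(ll_c) and ll_c >= ll - 1e-10 * (1.0 + abs(ll)):
                    proposal, ll_new, accepted = cand, ll_c, True
                    break
                frac *= 0.5
            if not accepted:
                converged = True
                break
        rel = abs(ll_new - ll) / (1.0 + abs(ll))
        params, ll = proposal, max(ll_new, ll)
        trace.append(ll)
        if rel < tol:
            converged = True
            break
    ses = _mu_standard_errors(params, xf, xr, priors, gap_grid)
    order = np.argsort(params.mu)
    comps = [EventComponent(float(params.mu[k]), float(params.delta[k]),
                            float(params.sf[k]), float(params.sr[k]),
                            float(params.w[k]), float(ses[k])) for k in order]
    pruned = False
    kept = [c for c in comps if c.weight >= 1e-3 and min(c.sigma_f, c.sigma_r) > 1.0 + 1e-9]
    if not kept:
        kept = comps  # degenerate: keep everything, flag
    if len(kept) < len(comps):
        pruned = True
        tot = sum(c.weight for c in kept)
        kept = [replace(c, weight=c.weight / tot) for c in kept]
        params = _Params([c.mu for c in kept], [c.delta for c in kept],
                         [c.sigma_f for c in kept], [c.sigma_r for c in kept],
                         [c.weight for c in kept])
        ll = _penalized_loglik(params, xf, xr, priors, gap_grid)
    return MixtureFit(len(kept), kept, ll, converged, n_iter, trace, pruned=pruned)


def select_K(region: CandidateRegion, Kmax: int = 3, priors: PeakPriors | None = None,
             map_profile: MappabilityProfile | None = None,
             tol: float = 1e-6, max_iter: int = 500) -> MixtureFit:
    """Fit K = 1..Kmax and return the BIC-optimal fit (5K-1 free parameters).

    Components closer than delta_hat/4 are merged after selection.
    """
    priors = priors or PeakPriors()
    n = region.n_reads
    best: MixtureFit | None = None
    best_bic = np.inf
    for K in range(1, Kmax + 1):
        if min(len(region.fwd), len(region.rev)) < 2 * K:
            break
        try:
            fit = fit_mixture(region, K, priors, map_profile, tol, max_iter)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(fit.loglik):
            continue
        p = 5 * fit.K - 1
        bic = -2.0 * fit.loglik + p * np.log(max(n, 2))
        if bic < best_bic:
            best, best_bic = fit, bic
    if best is None:
        fit = fit_mixture(region, 1, priors, map_profile, tol, max_iter)
        fit.degenerate_fallback = True
        return fit
    return _merge_close(best, region, priors, map_profile)


def _merge_close(fit: MixtureFit, region: CandidateRegion, priors: PeakPriors,
                 map_profile: MappabilityProfile | None) -> MixtureFit:
    comps = sorted(fit.components, key=lambda c: c.mu)
    delta_bar = float(np.average([c.delta for c in comps], weights=[c.weight for c in comps]))
    min_sep = delta_bar / 4.0
    merged: list[EventComponent] = []
    changed = False
    for c in comps:
        if merged and abs(c.mu - merged[-1].mu) < min_sep:
            prev = merged[-1]
            wsum = prev.weight + c.weight
            merged[-1] = EventComponent(
                (prev.mu * prev.weight + c.mu * c.weight) / wsum,
                (prev.delta * prev.weight + c.delta * c.weight) / wsum,
                (prev.sigma_f * prev.weight + c.sigma_f * c.weight) / wsum,
                (prev.sigma_r * prev.weight + c.sigma_r * c.weight) / wsum,
                wsum,
                min(prev.mu_se, c.mu_se))
            changed = True
        else:
            merged.append(c)
    if not changed:
        return fit
    params = _Params([c.mu for c in merged], [c.delta for c in merged],
                     [c.sigma_f for c in merged], [c.sigma_r for c in merged],
                     [c.weight for c in merged])
    gap_grid = _gap_grid(region, map_profile)
    ll = _penalized_loglik(params, region.fwd, region.rev, priors, gap_grid)
    return MixtureFit(len(merged), merged, ll, fit.converged, fit.n_iter,
                      fit.loglik_trace, pruned=fit.pruned, merged=True,
                      degenerate_fallback=fit.degenerate_fallback)


# ---------------------------------------------------------------------------
# Scoring, FDR, pipeline
# ---------------------------------------------------------------------------

def enrichment_score(fit: MixtureFit, region: CandidateRegion,
                     control_reads: Sequence[AlignedRead] | None = None,
                     lib_ratio: float = 1.0, eps: float = 0.5) -> list[BindingEvent]:
    """Per-component enrichment scores relative to an optional control sample.

    n_frag_est = w_k * (reads in region) / 2. With control, the score divides
    by the library-size-scaled control read count within mu +/- delta; without
    control the score is the estimated fragment count itself.
    """
    chrom = region.interval.chrom
    ctrl_pos = None
    if control_reads is not None:
        ctrl_pos = np.sort(np.asarray(
            [r.pos5 for r in control_reads if r.chrom == chrom], dtype=float))
    events: list[BindingEvent] = []
    for c in fit.components:
        n_frag = c.weight * region.n_reads / 2.0
        if ctrl_pos is None:
            score = n_frag
        else:
            lo, hi = c.mu - c.delta, c.mu + c.delta
            c_local = float(np.searchsorted(ctrl_pos, hi, side="right")
                            - np.searchsorted(ctrl_pos, lo, side="left"))
            score = n_frag / max(c_local / lib_ratio, eps)
        half = 1.96 * c.mu_se if np.isfinite(c.mu_se) else 0.0
        events.append(BindingEvent(chrom, c.mu, c.delta, float(score),
                                   c.mu - half, c.mu + half, n_frag,
                                   sigma_f=c.sigma_f, sigma_r=c.sigma_r))
    return events


class FdrCurve:
    """Empirical FDR as a step function of the enrichment score.

    FDR(s) = #{swapped >= s} / max(#{treatment >= s}, 1), clipped to [0, 1]
    and made monotone non-increasing in s.
    """

    def __init__(self, scores_treatment: Sequence[float], scores_swapped: Sequence[float]):
        t = np.sort(np.asarray(scores_treatment, dtype=float))
        if len(t) == 0:
            raise ValueError("empty treatment score list")
        sw = np.sort(np.asarray(scores_swapped, dtype=float))
        self.attained = np.unique(t)
        n_t = len(t) - np.searchsorted(t, self.attained, side="left")
        n_sw = len(sw) - np.searchsorted(sw, self.attained, side="left")
        raw = np.clip(n_sw / np.maximum(n_t, 1), 0.0, 1.0)
        self.fdr = np.minimum.accumulate(raw)  # ascending scores: running min
        self._t = t
        self._sw = sw

    def __call__(self, score: float) -> float:
        n_t = len(self._t) - np.searchsorted(self._t, score, side="left")
        n_sw = len(self._sw) - np.searchsorted(self._sw, score, side="left")
        raw = float(np.clip(n_sw / max(n_t, 1), 0.0, 1.0))
        i = np.searchsorted(self.attained, score, side="right") - 1
        if i >= 0:
            raw = min(raw, float(self.fdr[i]))
        return raw


def estimate_fdr(scores_treatment: Sequence[float],
                 scores_swapped: Sequence[float]) -> FdrCurve:
    return FdrCurve(scores_treatment, scores_swapped)


def call_peaks(treatment: Sequence[AlignedRead],
               control: Sequence[AlignedRead] | None = None,
               map_profile: MappabilityProfile | None = None,
               priors: PeakPriors | None = None,
               config: PeakConfig | None = None) -> list[BindingEvent]:
    """Full pipeline: segment -> select_K -> enrichment_score -> rank by score.

    Deterministic given inputs and configuration; ties in the ranking are
    broken by (chrom, mu).
    """
    priors = priors or PeakPriors()
    config = config or PeakConfig()
    if not treatment:
        return []
    regions = segment_regions(treatment, priors, config.min_fwd, config.min_rev,
                              config.window, config.step)
    lib_ratio = 1.0
    if control:
        lib_ratio = len(treatment) / max(len(control), 1)
    events: list[BindingEvent] = []
    for region in regions:
        fit = select_K(region, config.Kmax, priors, map_profile,
                       config.tol, config.max_iter)
        events.extend(enrichment_score(fit, region, control, lib_ratio, config.eps))
    events.sort(key=lambda e: (-e.score, e.chrom, e.mu))
    if config.top is not None:
        events = events[: config.top]
    return events


def attach_fdr(events: Sequence[BindingEvent], curve: FdrCurve) -> list[BindingEvent]:
    return [replace(e, fdr=curve(e.score)) for e in events]
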