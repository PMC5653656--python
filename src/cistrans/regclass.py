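"""Classification of sites into regulatory classes by constrained likelihood fits.

Each SNV-anchored site carries replicate read counts from two inbred parental
(F0) strains and allele-resolved counts from their F1 hybrids.  Parental counts
are modelled as negative binomial (a Poisson with Gamma-distributed mean of
shape ``r`` and scale ``p/(1-p)``, so the marginal mean is ``r*p/(1-p)``).
F1 allele counts are modelled beta-binomially, conditioning on the per-replicate
total ``n_j``: the strain-A allele count ``z_j ~ BetaBin(n_j, alpha, beta)``
with mean ``m = alpha/(alpha+beta)`` and concentration ``c = alpha+beta``.

Four nested hypotheses describe how regulatory variation acts:

``conserved``
    no divergence: shared F0 mean (``p_mu = p_nu``) and balanced alleles
    (``m = 1/2``).
``cis``
    allele-linked divergence: F0 means free, F1 allelic mean tied to the F0
    odds, ``m = odds(p_mu) / (odds(p_mu) + odds(p_nu))``.
``trans``
    divergence through the shared nuclear environment: F0 means free but the
    F1 alleles, sitting in the same nucleus, stay balanced (``m = 1/2``).
``cis_trans``
    both components: all parameters free.

The winning model per site is the one with the lowest BIC,
``k * ln(N) - 2 * lnL``, with ``N`` the number of replicate observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "nb_loglik",
    "nb_mean_mle",
    "betabin_loglik",
    "RegulatoryModelFit",
    "RegulatoryCall",
    "fit_regulatory_models",
    "classify_sites",
    "CLASSES",
]

CLASSES = ("conserved", "cis", "trans", "cis_trans")

#: BIC tie-break preference: fewer parameters first, conserved before others.
_MODEL_ORDER = {"conserved": 0, "cis": 1, "trans": 2, "cis_trans": 3}
_MODEL_K = {"conserved": 2, "cis": 3, "trans": 3, "cis_trans": 4}

_LOGIT_BOUND = 13.0
_LOGC_LO, _LOGC_HI = -3.0, 16.0


def _round_counts(x) -> np.ndarray:
    """Normalized counts are real-valued; discrete likelihoods act on the
    nearest integer (the rounding is part of the model contract)."""
    return np.rint(np.asarray(x, dtype=float)).astype(np.int64).clip(min=0)


def nb_loglik(counts, r: float, p: float) -> float:
    """Negative-binomial log-likelihood in the success-odds parameterization.

    ``counts ~ NB`` with size ``r`` and mean ``r * p / (1 - p)`` (the marginal
    of a Poisson whose mean is Gamma(shape ``r``, scale ``p/(1-p)``)).

    Parameters
    ----------
    counts : array-like of non-negative ints
    r : dispersion size parameter, ``> 0``
    p : success parameter in ``(0, 1)``
    """
    if not (np.isfinite(r) and np.isfinite(p)):
        raise ValueError("non-finite NB parameters")
    if not (r > 0 and 0.0 < p < 1.0):
        raise ValueError(f"invalid NB parameters r={r}, p={p}")
    x = _round_counts(counts)
    return float(stats.nbinom.logpmf(x, r, 1.0 - p).sum())


def nb_mean_mle(counts, r: float) -> float:
    """Closed-form MLE of ``p`` for fixed ``r``: moment matching of the mean.

    The NB log-likelihood in ``p`` is maximized where the model mean
    ``r*p/(1-p)`` equals the sample mean, hence ``p = mean / (r + mean)``.
    """
    m = float(np.mean(_round_counts(counts)))
    p = m / (r + m) if m > 0 else 1e-9
    return float(np.clip(p, 1e-9, 1.0 - 1e-9))


def betabin_loglik(k, n, mean: float, concentration: float) -> float:
    """Beta-binomial log-likelihood with mean/concentration parameters.

    ``alpha = mean * concentration``, ``beta = (1 - mean) * concentration``.
    """
    if not (0.0 < mean < 1.0 and concentration > 0):
        raise ValueError(f"invalid beta-binomial parameters mean={mean}, c={concentration}")
    k = _round_counts(k)
    n = _round_counts(n)
    if np.any(k > n):
        raise ValueError("allele count exceeds total count")
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(stats.betabinom.logpmf(k, n, a, b).sum())


def _betabin_ll_vec(k, n, mean, conc):
    # internal, pre-rounded arrays
    a = mean * conc
    b = (1.0 - mean) * conc
    return float(stats.betabinom.logpmf(k, n, a, b).sum())


class _NBPart:
    """NB log-likelihood in p with count-dependent terms precomputed.

    For fixed counts x and size r, ``ll(p) = K + n*r*ln(1-p) + sum(x)*ln(p)``
    with K collecting all gammaln terms; evaluation is O(1).
    """

    def __init__(self, x: np.ndarray, r: float):
        self.n = len(x)
        self.sum = float(x.sum())
        self.r = r
        self.K = float(special.gammaln(x + r).sum() - self.n * special.gammaln(r)
                       - special.gammaln(x + 1).sum())

    def ll(self, p: float) -> float:
        return self.K + self.n * self.r * math.log1p(-p) + self.sum * math.log(p)

    def mle(self) -> float:
        m = self.sum / self.n
        p = m / (self.r + m) if m > 0 else 1e-9
        return float(np.clip(p, 1e-9, 1.0 - 1e-9))


class _BetaBinPart:
    """Beta-binomial log-likelihood in (mean, concentration), with the
    binomial coefficients precomputed."""

    def __init__(self, z: np.ndarray, n: np.ndarray):
        self.z = z.astype(float)
        self.n = n.astype(float)
        self.nrep = len(z)
        self.K = float((special.gammaln(self.n + 1) - special.gammaln(self.z + 1)
                        - special.gammaln(self.n - self.z + 1)).sum())

    def ll(self, mean: float, conc: float) -> float:
        a = mean * conc
        b = (1.0 - mean) * conc
        return self.K + float(special.betaln(self.z + a, self.n - self.z + b).sum()
                              ) - self.nrep * float(special.betaln(a, b))


@dataclass
class RegulatoryModelFit:
    """One constrained maximum-likelihood fit."""

    model: str
    p_mu: float
    p_nu: float
    beta_mean: float
    concentration: float
    loglik: float
    k: int
    bic: float
    converged: bool = True


@dataclass
class RegulatoryCall:
    """Per-site classification outcome."""

    site_id: str
    winner: str                 # one of CLASSES or "unclassified"
    delta_bic: float            # runner-up BIC minus winner BIC (>= 0)
    fits: dict = field(default_factory=dict)

    @property
    def fit(self) -> RegulatoryModelFit | None:
        return self.fits.get(self.winner)


def _moment_start_beta(z, n):
    """Moment estimates of (mean, concentration) for beta-binomial starts."""
    tot = n.sum()
    m = z.sum() / tot if tot > 0 else 0.5
    m = float(np.clip(m, 0.02, 0.98))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, z / np.maximum(n, 1), np.nan)
    v = np.nanvar(frac)
    nbar = float(np.mean(n[n > 0])) if np.any(n > 0) else 1.0
    # solve Var(z/n) ~ m(1-m) * (1 + (nbar-1)/(c+1)) / nbar for c
    base = m * (1 - m) / nbar
    if v > base and nbar > 1:
        rho = (v - base) / (m * (1 - m) * (1 - 1 / nbar))
        rho = float(np.clip(rho, 1e-4, 0.999))
        c = (1 - rho) / rho
    else:
        c = 200.0
    return m, float(np.clip(c, math.exp(_LOGC_LO), math.exp(_LOGC_HI)))


def _fit_conc(bb: "_BetaBinPart", mean, c0):
    """1-D maximization of the beta-binomial likelihood over log-concentration."""
    def nll(logc):
        return -bb.ll(mean, math.exp(float(logc)))

    res = optimize.minimize_scalar(nll, bounds=(_LOGC_LO, _LOGC_HI), method="bounded",
                                   options={"xatol": 1e-10})
    # guard against a boundary/flat solution worse than the start
    if -nll(math.log(c0)) > -res.fun:
        return c0, bb.ll(mean, c0)
    c = math.exp(float(res.x))
    return c, -float(res.fun)


def _fit_mean_conc(bb: "_BetaBinPart", m0, c0):
    """2-D maximization over (logit mean, log concentration), multi-start."""
    def nll(theta):
        m = special.expit(float(np.clip(theta[0], -_LOGIT_BOUND, _LOGIT_BOUND)))
        c = math.exp(float(np.clip(theta[1], _LOGC_LO, _LOGC_HI)))
        return -bb.ll(m, c)

    starts = [(special.logit(m0), math.log(c0))]
    for dm in (-1.5, 1.5):
        for dc in (-2.0, 2.0):
            starts.append((special.logit(m0) + dm, math.log(c0) + dc))
    best = None
    for s in starts:
        res = optimize.minimize(nll, np.asarray(s, dtype=float), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    m = special.expit(float(np.clip(best.x[0], -_LOGIT_BOUND, _LOGIT_BOUND)))
    c = math.exp(float(np.clip(best.x[1], _LOGC_LO, _LOGC_HI)))
    return m, c, -float(best.fun), True


def _odds_mean(p_mu, p_nu):
    """The cis constraint: F1 allelic mean implied by the F0 odds."""
    omu = p_mu / (1.0 - p_mu)
    onu = p_nu / (1.0 - p_nu)
    return omu / (omu + onu)


def fit_regulatory_models(site, r: float, n_obs: int | None = None) -> RegulatoryCall:
    """Fit the four constrained models to one site and pick by BIC.

    Parameters
    ----------
    site : mapping with keys ``site_id``, ``f0_a``, ``f0_b``, ``f1_a``, ``f1_b``
        (replicate count vectors, normalized scale allowed).
    r : NB size parameter (reciprocal of the fitted dispersion) for this site.
    n_obs : BIC sample size; defaults to the number of replicate observations
        (n F0 strain A + n F0 strain B + n F1).

    Returns
    -------
    RegulatoryCall with all four fits; ``winner == "unclassified"`` when the
    site carries no information (all-zero F0 or all-zero F1 totals) or no fit
    converged.
    """
    xa = _round_counts(site["f0_a"])
    xb = _round_counts(site["f0_b"])
    z = _round_counts(site["f1_a"])
    n2 = _round_counts(site["f1_b"]) + z
    z = np.minimum(z, n2)
    site_id = str(site["site_id"])

    if n_obs is None:
        n_obs = len(xa) + len(xb) + len(z)
    ln_n = math.log(n_obs)

    if (xa.sum() + xb.sum() == 0) or (n2.sum() == 0):
        return RegulatoryCall(site_id=site_id, winner="unclassified",
                              delta_bic=float("nan"))

    m0, c0 = _moment_start_beta(z, n2)
    nb_a = _NBPart(xa, r)
    nb_b = _NBPart(xb, r)
    bb = _BetaBinPart(z, n2)
    p_a = nb_a.mle()
    p_b = nb_b.mle()
    p_shared = _NBPart(np.concatenate([xa, xb]), r).mle()

    ll_a = nb_a.ll(p_a)
    ll_b = nb_b.ll(p_b)
    ll_shared = nb_a.ll(p_shared) + nb_b.ll(p_shared)

    fits: dict[str, RegulatoryModelFit] = {}

    def add(model, p_mu, p_nu, mean, conc, ll, converged=True):
        k = _MODEL_K[model]
        fits[model] = RegulatoryModelFit(
            model=model, p_mu=p_mu, p_nu=p_nu, beta_mean=mean,
            concentration=conc, loglik=ll, k=k,
            bic=k * ln_n - 2.0 * ll, converged=converged)

    # conserved: shared p, m = 1/2, free c
    c_hat, ll_f1 = _fit_conc(bb, 0.5, c0)
    add("conserved", p_shared, p_shared, 0.5, c_hat, ll_shared + ll_f1)

    # trans: free p_mu, p_nu, m = 1/2, free c
    add("trans", p_a, p_b, 0.5, c_hat, ll_a + ll_b + ll_f1)

    # cis_trans: everything free
    m_ct, c_ct, ll_ct, conv = _fit_mean_conc(bb, m0, c0)
    add("cis_trans", p_a, p_b, m_ct, c_ct, ll_a + ll_b + ll_ct, conv)

    # cis: m tied to the F0 odds; joint over (logit p_mu, logit p_nu, log c)
    def cis_nll(theta):
        pm = special.expit(float(np.clip(theta[0], -_LOGIT_BOUND, _LOGIT_BOUND)))
        pn = special.expit(float(np.clip(theta[1], -_LOGIT_BOUND, _LOGIT_BOUND)))
        c = math.exp(float(np.clip(theta[2], _LOGC_LO, _LOGC_HI)))
        m = float(np.clip(_odds_mean(pm, pn), 1e-9, 1 - 1e-9))
        return -(nb_a.ll(pm) + nb_b.ll(pn) + bb.ll(m, c))

    starts = [
        (special.logit(p_a), special.logit(p_b), math.log(c0)),
        # start consistent with the F1 imbalance: scale the shared odds
        (special.logit(p_shared) + special.logit(m0) / 2.0,
         special.logit(p_shared) - special.logit(m0) / 2.0,
         math.log(c0)),
    ]
    best = None
    for s in starts:
        s = np.clip(np.asarray(s, dtype=float), -_LOGIT_BOUND + 1, _LOGIT_BOUND - 1)
        res = optimize.minimize(cis_nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    pm = special.expit(float(np.clip(best.x[0], -_LOGIT_BOUND, _LOGIT_BOUND)))
    pn = special.expit(float(np.clip(best.x[1], -_LOGIT_BOUND, _LOGIT_BOUND)))
    c_cis = math.exp(float(np.clip(best.x[2], _LOGC_LO, _LOGC_HI)))
    add("cis", pm, pn, _odds_mean(pm, pn), c_cis, -float(best.fun), True)

    ranked = sorted(fits.values(), key=lambda f: (f.bic, f.k, _MODEL_ORDER[f.model]))
    winner, runner = ranked[0], ranked[1]
    return RegulatoryCall(site_id=site_id, winner=winner.model,
                          delta_bic=runner.bic - winner.bic, fits=fits)


def calls_to_frame(calls: list[RegulatoryCall]) -> pd.DataFrame:
    """Flatten calls into the result table written by the pipeline."""
    rows = []
    for call in calls:
        row = {"site_id": call.site_id, "class": call.winner,
               "delta_bic": call.delta_bic}
        f = call.fit
        row.update({
            "p_mu": f.p_mu if f else np.nan,
            "p_nu": f.p_nu if f else np.nan,
            "beta_mean": f.beta_mean if f else np.nan,
            "concentration": f.concentration if f else np.nan,
        })
        for model in CLASSES:
            mf = call.fits.get(model)
            row[f"loglik_{model}"] = mf.loglik if mf else np.nan
            row[f"bic_{model}"] = mf.bic if mf else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_sites(site_table, dispersion, n_obs: int | None = None) -> pd.DataFrame:
    """Classify every site in a table.

    Parameters
    ----------
    site_table : SiteTable (see :mod:`cistrans.io`)
    dispersion : DispersionModel, mapping of site_id -> r, or a scalar r
        applied to all sites.
    n_obs : optional BIC sample-size override.

    Returns
    -------
    DataFrame with one row per site: class, delta_bic, parameter estimates and
    per-model log-likelihood / BIC columns.
    """
    from .preprocess import DispersionModel  # local import to avoid a cycle

    if isinstance(dispersion, DispersionModel):
        r_lookup = dispersion.r_by_site
        get_r = lambda sid: r_lookup[sid]
    elif np.isscalar(dispersion):
        get_r = lambda sid: float(dispersion)
    else:
        get_r = lambda sid: float(dispersion[sid])

    calls = []
    for site in site_table.iter_sites():
        calls.append(fit_regulatory_models(site, get_r(site["site_id"]), n_obs=n_obs))
    return calls_to_frame(calls)
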