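"""Inheritance-mode assignment for total F1 occupancy at non-conserved sites.

Whereas the regulatory classification compares the F1 *allelic ratio* with the
F0 strain ratio, inheritance concerns the *total* F1 signal: additive
inheritance means the combined occupancy of the two F1 alleles equals the
midparent level, dominant inheritance means it equals one parent.

Parents are ordered by median replicate intensity into a high (``pmax``) and a
low (``pmin``) parent.  Normalized replicate counts are modelled as negative
binomial with a supplied size ``r``; the mean parameters ``S_pmax``,
``S_pmin`` and ``S_o`` (offspring) enter through the success-odds
parameterization (mean = ``r * S / (1 - S)``).  Two equality-constrained
models (``S_pmax = S_o`` and ``S_pmin = S_o``) are each compared against the
free model by BIC:

* both equalities win        -> the offspring is indistinguishable from both
  parents; the site is excluded (``ambiguous``);
* exactly one equality wins  -> dominant toward that parent;
* neither wins               -> additive; if the mean F1 level then falls
  outside the parental range the site is over-/under-dominant.

A separation filter guards against mistaking measurement noise for dominance:
parental means must differ by at least ``max(2 * SD, 19)`` normalized counts,
where SD is the pooled within-strain standard deviation of replicate
intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regclass import nb_loglik, nb_mean_mle, _round_counts

logger = logging.getLogger("cistrans")

__all__ = ["InheritanceCall", "fit_inheritance", "classify_overdominance",
           "classify_inheritance"]

MODES = ("additive", "dominant_high_parent", "dominant_low_parent",
         "overdominant", "underdominant", "excluded_equal_parents",
         "excluded_low_separation", "ambiguous")


@dataclass
class InheritanceCall:
    site_id: str
    mode: str
    s_pmax: float = float("nan")
    s_pmin: float = float("nan")
    s_o: float = float("nan")
    mean_pmax: float = float("nan")
    mean_pmin: float = float("nan")
    mean_f1: float = float("nan")
    separation: float = float("nan")
    bics: dict = field(default_factory=dict)
    high_parent: str = ""        # "A" or "B"


def _nb_fit_ll(counts, r):
    p = nb_mean_mle(counts, r)
    return p, nb_loglik(counts, r, p)


def fit_inheritance(site, r: float, min_separation: float = 19.0,
                    check_overdominance: bool = True) -> InheritanceCall:
    """Fit the dominant/additive model family to one site.

    ``site`` is a mapping with ``site_id``, ``f0_a``, ``f0_b``, ``f1_a``,
    ``f1_b`` (normalized replicate counts).  ``r`` is the NB size.
    """
    xa = np.asarray(site["f0_a"], dtype=float)
    xb = np.asarray(site["f0_b"], dtype=float)
    y = np.asarray(site["f1_a"], dtype=float) + np.asarray(site["f1_b"], dtype=float)
    sid = str(site["site_id"])

    med_a, med_b = float(np.median(xa)), float(np.median(xb))
    if med_a == med_b:
        return InheritanceCall(site_id=sid, mode="excluded_equal_parents")
    if med_a > med_b:
        xmax, xmin, high = xa, xb, "A"
    else:
        xmax, xmin, high = xb, xa, "B"

    # separation filter: pooled within-strain SD of replicate intensities
    sd = math.sqrt((np.var(xa, ddof=1) * (len(xa) - 1)
                    + np.var(xb, ddof=1) * (len(xb) - 1))
                   / (len(xa) + len(xb) - 2))
    sep = abs(float(np.mean(xa)) - float(np.mean(xb)))
    call = InheritanceCall(site_id=sid, mode="", separation=sep,
                           mean_pmax=float(np.mean(xmax)),
                           mean_pmin=float(np.mean(xmin)),
                           mean_f1=float(np.mean(y)), high_parent=high)
    if sep < max(2.0 * sd, min_separation):
        call.mode = "excluded_low_separation"
        return call

    n_obs = len(xa) + len(xb) + len(y)
    ln_n = math.log(n_obs)

    s_max, ll_max = _nb_fit_ll(xmax, r)
    s_min, ll_min = _nb_fit_ll(xmin, r)
    s_o, ll_o = _nb_fit_ll(y, r)
    call.s_pmax, call.s_pmin, call.s_o = s_max, s_min, s_o

    # free model: 3 mean parameters
    bic_add = 3 * ln_n - 2.0 * (ll_max + ll_min + ll_o)
    # S_pmax = S_o shared: 2 parameters
    s_sh, ll_sh = _nb_fit_ll(np.concatenate([xmax, y]), r)
    bic_dom_high = 2 * ln_n - 2.0 * (ll_sh + ll_min)
    # S_pmin = S_o shared
    s_sl, ll_sl = _nb_fit_ll(np.concatenate([xmin, y]), r)
    bic_dom_low = 2 * ln_n - 2.0 * (ll_sl + ll_max)

    call.bics = {"additive": bic_add, "dominant_high_parent": bic_dom_high,
                 "dominant_low_parent": bic_dom_low}

    high_wins = bic_dom_high < bic_add
    low_wins = bic_dom_low < bic_add
    if high_wins and low_wins:
        call.mode = "ambiguous"   # offspring indistinguishable from both parents
        return call
    if high_wins:
        call.mode = "dominant_high_parent"
        return call
    if low_wins:
        call.mode = "dominant_low_parent"
        return call

    call.mode = "additive"
    if check_overdominance:
        od = classify_overdominance(site)
        if od != "neither":
            call.mode = od
    return call


def classify_overdominance(site) -> str:
    """Over/under-dominance from replicate means.

    Precondition (enforced by the caller): both parent-equality models were
    rejected.  Under-dominant when the mean F1 total is below both parental
    means, over-dominant when above both, otherwise ``neither``.
    """
    mean_a = float(np.mean(np.asarray(site["f0_a"], dtype=float)))
    mean_b = float(np.mean(np.asarray(site["f0_b"], dtype=float)))
    y = np.asarray(site["f1_a"], dtype=float) + np.asarray(site["f1_b"], dtype=float)
    mean_f1 = float(np.mean(y))
    if mean_f1 < min(mean_a, mean_b):
        return "underdominant"
    if mean_f1 > max(mean_a, mean_b):
        return "overdominant"
    return "neither"


def classify_inheritance(site_table, calls: pd.DataFrame, dispersion,
                         min_separation: float = 19.0,
                         min_delta_bic: float = 1.0,
                         classes: tuple = ("cis", "trans")) -> pd.DataFrame:
    """Inheritance calls for all confidently classified non-conserved sites.

    ``calls`` is the regulatory-class table; only sites whose class is in
    ``classes`` with ``delta_bic > min_delta_bic`` are tested (others are not
    reported).  ``dispersion`` is a DispersionModel, mapping, or scalar ``r``.
    """
    from .preprocess import DispersionModel

    if isinstance(dispersion, DispersionModel):
        get_r = lambda sid: dispersion.r_by_site[sid]
    elif np.isscalar(dispersion):
        get_r = lambda sid: float(dispersion)
    else:
        get_r = lambda sid: float(dispersion[sid])

    by_id = calls.set_index("site_id")
    rows = []
    n_skipped = 0
    for site in site_table.iter_sites():
        sid = site["site_id"]
        if sid not in by_id.index:
            continue
        rec = by_id.loc[sid]
        if rec["class"] not in classes or not rec["delta_bic"] > min_delta_bic:
            n_skipped += 1
            continue
        call = fit_inheritance(site, get_r(sid), min_separation=min_separation)
        rows.append({
            "site_id": sid, "class": rec["class"], "mode": call.mode,
            "s_pmax": call.s_pmax, "s_pmin": call.s_pmin, "s_o": call.s_o,
            "mean_pmax": call.mean_pmax, "mean_pmin": call.mean_pmin,
            "mean_f1": call.mean_f1, "separation": call.separation,
            "high_parent": call.high_parent,
            **{f"bic_{k}": v for k, v in call.bics.items()},
        })
    logger.info("classify_inheritance: %d sites tested, %d skipped "
                "(class/confidence filter)", len(rows), n_skipped)
    cols = ["site_id", "class", "mode", "s_pmax", "s_pmin", "s_o", "mean_pmax",
            "mean_pmin", "mean_f1", "separation", "high_parent",
            "bic_additive", "bic_dominant_high_parent", "bic_dominant_low_parent"]
    return pd.DataFrame(rows, columns=cols if not rows else None)
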