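"""Lineage-specific sites: cis vs cis-trans, compensatory/diversifying,
apomorphic/plesiomorphic.

A site is lineage-specific when binding is essentially confined to one strain
in the parents *and* to the corresponding allele in the hybrids (allelic
proportion beyond 0.95 / below 0.05 in both generations).  At such sites only
one F1 allele is bound, so under a purely cis mechanism the F1 total is half
the bound parent's level; a deviation from that 2:1 ratio indicates an
additional trans influence.  The test doubles the F1 totals (``2y``) and fits
negative-binomial models sharing (cis) or freeing (cis-trans) the mean against
the bound parent's F0 counts, selecting by BIC.  (Doubling a count changes its
variance under a count model; the doubled form is kept deliberately as the
method's definition.)

At cis-trans sites bound on both alleles, the trans component either shrinks
the parental difference in the hybrid (compensatory) or amplifies it
(diversifying), measured on log2 ratios.  With an outgroup presence flag,
lineage-specific sites are polarized into gains (apomorphic: absent in the
outgroup) and losses (plesiomorphic: present in the outgroup and the bound
lineage).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .regclass import nb_loglik, nb_mean_mle

logger = logging.getLogger("cistrans")

__all__ = [
    "call_lineage_specific",
    "fit_lineage_models",
    "classify_compensatory",
    "classify_apomorphy",
    "compensatory_balance_test",
    "classify_lineage",
]


def call_lineage_specific(site, cutoff: float = 0.95) -> str:
    """Flag a site as strain-specific from F0 and F1 mean proportions.

    Returns ``"A"`` (strain-A-specific), ``"B"`` or ``"shared"``.  The
    proportion is A / (A + B) on replicate means; both the F0 and the F1
    proportion must clear the cutoff on the same side.
    """
    f0a = float(np.mean(np.asarray(site["f0_a"], dtype=float)))
    f0b = float(np.mean(np.asarray(site["f0_b"], dtype=float)))
    f1a = float(np.mean(np.asarray(site["f1_a"], dtype=float)))
    f1b = float(np.mean(np.asarray(site["f1_b"], dtype=float)))
    if (f0a + f0b == 0) or (f1a + f1b == 0):
        logger.info("call_lineage_specific: site %s has a zero F0 or F1 "
                    "total; left unflagged", site.get("site_id", "?"))
        return "shared"
    r0 = f0a / (f0a + f0b)
    r1 = f1a / (f1a + f1b)
    lo = 1.0 - cutoff
    if r0 > cutoff and r1 > cutoff:
        return "A"
    if r0 < lo and r1 < lo:
        return "B"
    return "shared"


def fit_lineage_models(site, r: float, flag: str | None = None) -> dict:
    """Cis vs cis-trans at a lineage-specific site by BIC on doubled F1 counts.

    ``x`` is the bound strain's F0 replicate vector and ``y`` the F1 totals;
    the models compare ``x`` and ``2y`` as negative binomial with a shared
    mean (cis, 1 parameter) or free means (cis-trans, 2 parameters).

    Returns a dict with keys ``mechanism`` ("cis" | "cis_trans" |
    "unresolved"), ``s_pmax``, ``s_o``, ``delta_bic`` and both BICs.
    """
    flag = flag or call_lineage_specific(site)
    if flag == "shared":
        return {"mechanism": "unresolved", "s_pmax": float("nan"),
                "s_o": float("nan"), "delta_bic": float("nan"),
                "bic_cis": float("nan"), "bic_cis_trans": float("nan")}
    x = np.asarray(site["f0_a" if flag == "A" else "f0_b"], dtype=float)
    y = np.asarray(site["f1_a"], dtype=float) + np.asarray(site["f1_b"], dtype=float)
    y2 = 2.0 * y
    n_obs = len(x) + len(y)
    ln_n = math.log(n_obs)

    s_sh = nb_mean_mle(np.concatenate([x, y2]), r)
    ll_cis = nb_loglik(x, r, s_sh) + nb_loglik(y2, r, s_sh)
    bic_cis = 1 * ln_n - 2.0 * ll_cis

    s_p = nb_mean_mle(x, r)
    s_o = nb_mean_mle(y2, r)
    ll_ct = nb_loglik(x, r, s_p) + nb_loglik(y2, r, s_o)
    bic_ct = 2 * ln_n - 2.0 * ll_ct

    mech = "cis" if bic_cis <= bic_ct else "cis_trans"
    return {"mechanism": mech, "s_pmax": s_p, "s_o": s_o,
            "delta_bic": abs(bic_ct - bic_cis),
            "bic_cis": bic_cis, "bic_cis_trans": bic_ct}


def classify_compensatory(site, pseudocount: float = 0.5) -> str:
    """Compensatory vs diversifying at a both-allele-bound cis-trans site.

    Compares the magnitude of the F1 log2 allelic ratio with the F0 log2
    strain ratio (replicate means, pseudocount for zeros): trans effects that
    shrink the parental difference in the hybrid are compensatory, effects
    that amplify it are diversifying.  Exact ties are excluded.
    """
    f0a = float(np.mean(np.asarray(site["f0_a"], dtype=float)))
    f0b = float(np.mean(np.asarray(site["f0_b"], dtype=float)))
    f1a = float(np.mean(np.asarray(site["f1_a"], dtype=float)))
    f1b = float(np.mean(np.asarray(site["f1_b"], dtype=float)))
    if min(f0a, f0b, f1a, f1b) <= 0:
        logger.info("classify_compensatory: zero mean count at site %s; "
                    "pseudocount %.1f applied", site.get("site_id", "?"),
                    pseudocount)
    lf0 = abs(math.log2((f0a + pseudocount) / (f0b + pseudocount)))
    lf1 = abs(math.log2((f1a + pseudocount) / (f1b + pseudocount)))
    if lf1 < lf0:
        return "compensatory"
    if lf1 > lf0:
        return "diversifying"
    return "tie_excluded"


def classify_apomorphy(flag: str, outgroup_present: bool) -> str:
    """Polarize a strain-specific site with an outgroup presence flag.

    A site bound in exactly one ingroup lineage is a lineage-specific *gain*
    (apomorphic) when the outgroup lacks it, and a *loss* in the unbound
    lineage (plesiomorphic) when the outgroup shares it.
    """
    if flag not in ("A", "B"):
        warnings.warn("classify_apomorphy called on a non-lineage-specific "
                      "site; returning 'unresolved'")
        return "unresolved"
    return "plesiomorphic" if outgroup_present else "apomorphic"


def compensatory_balance_test(labels) -> dict:
    """Two-sided exact binomial test of compensatory vs diversifying balance.

    ``labels`` is an iterable of "compensatory" / "diversifying" (ties
    ignored).  Returns the proportion compensatory and the exact p-value
    against 0.5.
    """
    labels = [l for l in labels if l in ("compensatory", "diversifying")]
    if not labels:
        raise ValueError("no compensatory/diversifying labels supplied")
    k = sum(1 for l in labels if l == "compensatory")
    n = len(labels)
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return {"n": n, "n_compensatory": k, "proportion": k / n,
            "p_value": float(res.pvalue)}


def classify_lineage(site_table, dispersion, outgroup: dict | pd.Series | None = None,
                     calls: pd.DataFrame | None = None,
                     cutoff: float = 0.95) -> pd.DataFrame:
    """Full lineage stage over a table: flags, mechanisms, apomorphy, and
    compensatory labels for shared cis-trans sites.

    ``outgroup`` maps site_id -> bool presence; sites without an entry stay
    ``unresolved``.  ``calls`` (regulatory classes) gates the compensatory
    labels to cis-trans sites.
    """
    from .preprocess import DispersionModel

    if isinstance(dispersion, DispersionModel):
        get_r = lambda sid: dispersion.r_by_site[sid]
    elif np.isscalar(dispersion):
        get_r = lambda sid: float(dispersion)
    else:
        get_r = lambda sid: float(dispersion[sid])

    class_by_id = {} if calls is None else dict(zip(calls["site_id"], calls["class"]))
    rows = []
    for site in site_table.iter_sites():
        sid = site["site_id"]
        flag = call_lineage_specific(site, cutoff=cutoff)
        row = {"site_id": sid, "lineage": flag, "mechanism": "",
               "s_pmax": float("nan"), "s_o": float("nan"),
               "delta_bic": float("nan"), "apomorphy": "unresolved",
               "compensatory": ""}
        if flag in ("A", "B"):
            fit = fit_lineage_models(site, get_r(sid), flag=flag)
            row.update({k: fit[k] for k in ("mechanism", "s_pmax", "s_o",
                                            "delta_bic")})
            if outgroup is not None and sid in outgroup:
                row["apomorphy"] = classify_apomorphy(flag, bool(outgroup[sid]))
        elif class_by_id.get(sid) == "cis_trans":
            row["compensatory"] = classify_compensatory(site)
        rows.append(row)
    return pd.DataFrame(rows)
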