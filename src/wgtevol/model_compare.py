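"""Nested likelihood-ratio tests between fitted loss-model variants.

The model family is nested as NULL < ONE_DOM < G3 < {G3_ROOTSPEC, G3_ROOT}:
each restriction pins fractionation or root parameters at their neutral
values (f = 1; root parameters shared; instantaneous arrival).  Twice the
log-likelihood gain is referred to a chi-square distribution whose degrees of
freedom are the difference in free loss-model parameter counts (branch
lengths and synteny persistence are common to both models and cancel).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .loss_model import LossModelSpec, Variant, free_parameter_count

#: direct restriction arrows of the model family
_DIRECT_NESTINGS = {
    (Variant.NULL, Variant.ONE_DOM),
    (Variant.ONE_DOM, Variant.G3),
    (Variant.G3, Variant.G3_ROOTSPEC),
    (Variant.G3, Variant.G3_ROOT),
}


def is_nested(nested: Variant, general: Variant) -> bool:
    """True if ``nested``'s parameter space is a restriction of ``general``'s
    (reflexive-transitive closure of the direct restriction arrows)."""
    nested, general = Variant(nested), Variant(general)
    if nested == general:
        return True
    frontier = {nested}
    while frontier:
        nxt = {b for (a, b) in _DIRECT_NESTINGS if a in frontier}
        if general in nxt:
            return True
        frontier = nxt - frontier
    return False


def restriction_map(nested: Variant, general: Variant) -> dict[str, float] | None:
    """Parameter values pinning ``general`` down to ``nested``.

    Returns the constraint dictionary, or None for non-nested pairs.  Used to
    machine-check the nesting audit: applying the constraints to the general
    model must reproduce the nested model's generator.
    """
    if not is_nested(nested, general):
        return None
    nested, general = Variant(nested), Variant(general)
    pins: dict[str, float] = {}
    free_nested = set()
    from .loss_model import free_parameter_names
    free_nested = set(free_parameter_names(nested))
    for name in free_parameter_names(general):
        if name in free_nested:
            continue
        if name.startswith("f") or name.startswith("root_f"):
            pins[name] = 1.0
        elif name == "root_sigma":
            pins[name] = None  # tied to sigma, handled by caller
        elif name == "tau":
            pins[name] = np.inf  # instantaneous arrival (boundary at infinity)
        elif name.startswith("beta"):
            pins[name] = 0.0
    return pins


@dataclass(frozen=True)
class LrtResult:
    """A likelihood-ratio comparison between two nested fitted models."""

    nested_variant: Variant
    general_variant: Variant
    lnL_nested: float
    lnL_general: float
    statistic: float
    df: int
    p_value: float


def lrt(fit_nested, fit_general, tol: float = 1e-6) -> LrtResult:
    """Likelihood-ratio test of a nested against a more general fitted model.

    The reference distribution is a plain chi-square, matching standard
    practice for this model family; note that fractionation factors restricted
    to f = 1 sit on the boundary of their range under the null, which makes
    the test conservative there.
    """
    nv, gv = Variant(fit_nested.variant), Variant(fit_general.variant)
    if nv == gv or not is_nested(nv, gv):
        raise ValueError(f"{nv.value} is not nested within {gv.value}")
    for f in (fit_nested, fit_general):
        if not getattr(f, "converged", True):
            import warnings
            warnings.warn(f"LRT on a fit flagged as non-converged ({Variant(f.variant).value})",
                          RuntimeWarning)
    stat = 2.0 * (fit_general.lnL - fit_nested.lnL)
    if stat < -tol:
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): the general model fits worse; "
            "optimizer failure")
    stat = max(stat, 0.0)
    df = free_parameter_count(gv) - free_parameter_count(nv)
    p = float(scipy.stats.chi2.sf(stat, df))
    return LrtResult(nested_variant=nv, general_variant=gv,
                     lnL_nested=fit_nested.lnL, lnL_general=fit_general.lnL,
                     statistic=stat, df=df, p_value=p)
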