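"""Hill-equation regulation kinetics.

The rate of expression of a gene is its production constant times a
dimensionless regulation strength in [0, 1], assembled from the Hill
terms t_i = (K_i * c_i)**eta_i of its regulators:

    strength = N / Dn
    Dn       = prod over ALL regulators (1 + t_i)
    S_suff   = prod over sufficient activators (1 + t_i) - 1   (1 if none)
    P_nec    = prod over necessary activators t_i              (1 if none)
    N        = basal + S_suff * P_nec   if any activator exists,
               basal                    otherwise.

Necessary activators combine as AND logic, sufficient activators as OR
logic, and inhibitors always multiply into the denominator (AND).  The
single- and two-regulator special cases (single activation/inhibition,
AND, OR, NOR, NIMPLY) all fall out of this one composition rule.

``S_suff`` is accumulated incrementally (s <- s*(1+t) + t) so that the
expanded polynomial t1*t2 + t1 + t2 is summed with only positive
additions — no cancellation for small terms.  If the direct ratio
overflows, an algebraically identical product of bounded factors is used
for the affected entries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .grm import GRM, GeneSpec, basal_level

__all__ = ["hill_term", "regulation_strength", "strength_from_regs", "gene_rate"]


def hill_term(c, bind_const: float, hill_coeff: float):
    """Dimensionless Hill term (K * c)**eta for concentration(s) c >= 0."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration in Hill term")
    t = np.power(bind_const * c, hill_coeff)
    return t if t.ndim else float(t)


def _as_terms(terms) -> list:
    return [np.asarray(t, dtype=float) for t in terms]


def regulation_strength(
    necessary: Sequence = (),
    sufficient: Sequence = (),
    negative: Sequence = (),
    basal: float = 1.0,
):
    """Compose regulator Hill terms into a strength in [0, 1].

    Parameters are sequences of precomputed Hill terms (scalars or
    broadcast-compatible arrays) for the necessary activators, the
    sufficient activators, and the inhibitors, plus the basal level
    (0 or 1, derived from the network; see ``grm.basal_level``).
    """
    nec, suf, neg = _as_terms(necessary), _as_terms(sufficient), _as_terms(negative)
    for t in (*nec, *suf, *neg):
        if np.any(t < 0):
            raise ValueError("negative Hill term")

    with np.errstate(invalid="ignore", over="ignore"):
        dn = 1.0
        for t in (*nec, *suf, *neg):
            dn = dn * (1.0 + t)
        if nec or suf:
            s = 0.0 if suf else 1.0
            for t in suf:
                s = s * (1.0 + t) + t
            p = 1.0
            for t in nec:
                p = p * t
            n = basal + s * p
        else:
            n = basal
        strength = np.asarray(n / dn, dtype=float)

    bad = ~np.isfinite(strength)
    if np.any(bad):
        strength = np.where(bad, _bounded_strength(nec, suf, neg, basal), strength)
    return strength if strength.ndim else float(strength)


def _bounded_strength(nec, suf, neg, basal):
    """Overflow-safe reformulation: every factor lies in [0, 1].

    strength = basal/Dn + [1 - prod_suff 1/(1+t)] * [prod_nec t/(1+t)]
               * [prod_neg 1/(1+t)]          (second term only if activators)
    """
    inv_all = 1.0
    for t in (*nec, *suf, *neg):
        inv_all = inv_all * _inv1p(t)
    out = basal * inv_all
    if nec or suf:
        suff_factor = 1.0
        if suf:
            inv_suf = 1.0
            for t in suf:
                inv_suf = inv_suf * _inv1p(t)
            suff_factor = 1.0 - inv_suf
        nec_factor = 1.0
        for t in nec:
            nec_factor = nec_factor * _ratio(t)
        neg_inv = 1.0
        for t in neg:
            neg_inv = neg_inv * _inv1p(t)
        out = out + suff_factor * nec_factor * neg_inv
    return out


def _inv1p(t):
    with np.errstate(over="ignore"):
        return np.where(np.isinf(t), 0.0, 1.0 / (1.0 + t))


def _ratio(t):
    with np.errstate(invalid="ignore", over="ignore"):
        return np.where(np.isinf(t), 1.0, t / (1.0 + t))


def strength_from_regs(grm: GRM, gene_name: str, concentrations) -> float:
    """Regulation strength of one gene given a mapping name -> concentration.

    Convenience wrapper used by tests and diagnostics; the simulator
    compiles an equivalent vectorized plan.
    """
    gene = grm.gene(gene_name)
    regs = grm.incoming(gene_name)
    nec, suf, neg = [], [], []
    for r in regs:
        t = hill_term(concentrations[r.source], r.bind_const, r.hill_coeff)
        if r.sign == "negative":
            neg.append(t)
        elif r.grouping == "sufficient":
            suf.append(t)
        else:
            nec.append(t)
    basal = basal_level(gene, grm.regulations)
    return regulation_strength(nec, suf, neg, basal)


def gene_rate(gene: GeneSpec, strength, concentration, laplacian=0.0):
    """Instantaneous rate of concentration change of one gene:

    rho * strength - lambda * c + D * lap(c)
    """
    return (
        gene.production * strength
        - gene.decay * concentration
        + gene.diffusion * laplacian
    )
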