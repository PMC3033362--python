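"""Dependence between the gap-junction and chemical networks.

Likelihood ratios compare the conditional frequencies of a pair's chemical
state (absent / unidirectional / bidirectional) given the presence or
absence of a gap junction on the same pair, and degree-sequence Pearson
correlations are tested against permutation nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .wiring import AdjacencyNetwork

__all__ = ["LikelihoodRatios", "likelihood_ratios", "degree_correlation_table"]

CHEM_STATES = ("absent", "unidirectional", "bidirectional")


@dataclass
class LikelihoodRatios:
    ratios: dict[str, float]            # state -> LR (inf flagged, not raised)
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_given_gap: dict[str, float]
    p_given_no_gap: dict[str, float]
    n_gap_pairs: int
    n_no_gap_pairs: int
    undefined: set[str]                 # states with a zero denominator


def _pair_states(
    gap: AdjacencyNetwork, chem: AdjacencyNetwork, subset: str, gaba: set[str] | None
):
    if gap.names != chem.names:
        raise ValueError("gap and chem networks must share the same neuron index")
    n = gap.n
    G = gap.binary()
    G = np.maximum(G, G.T)
    C = chem.binary()
    iu, ju = np.triu_indices(n, k=1)
    gap_present = G[iu, ju] > 0
    fwd = C[iu, ju] > 0
    bwd = C[ju, iu] > 0

    if subset == "all":
        chem_state = np.where(fwd & bwd, 2, np.where(fwd | bwd, 1, 0))
        keep = np.ones(len(iu), dtype=bool)
    elif subset == "gaba_presynaptic":
        if gaba is None:
            raise ValueError("gaba_presynaptic subset requires the GABAergic name set")
        is_gaba = np.array([nm in gaba for nm in gap.names])
        gi, gj = is_gaba[iu], is_gaba[ju]
        keep = gi | gj
        # the chemical connections *from* the GABAergic member(s) define the state
        out_g = (gi & fwd) | (gj & bwd)          # GABA member presynaptic
        back = (gi & bwd) | (gj & fwd)           # return connection onto it
        chem_state = np.where(out_g & back, 2, np.where(out_g | back, 1, 0))
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return gap_present[keep], chem_state[keep]


def _ratios_from(gap_present: np.ndarray, chem_state: np.ndarray):
    n_gap = int(gap_present.sum())
    n_nogap = int((~gap_present).sum())
    p_gap, p_nogap, lrs = {}, {}, {}
    undefined = set()
    for s, name in enumerate(CHEM_STATES):
        pg = (chem_state[gap_present] == s).mean() if n_gap else np.nan
        pn = (chem_state[~gap_present] == s).mean() if n_nogap else np.nan
        p_gap[name], p_nogap[name] = float(pg), float(pn)
        if not np.isfinite(pn) or pn == 0:
            lrs[name] = float("inf") if pg > 0 else float("nan")
            undefined.add(name)
        else:
            lrs[name] = float(pg / pn)
    return lrs, p_gap, p_nogap, n_gap, n_nogap, undefined


def likelihood_ratios(
    gap: AdjacencyNetwork,
    chem: AdjacencyNetwork,
    subset: str = "all",
    gaba: set[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> LikelihoodRatios:
    """LR(s) = P(chem state s | gap present) / P(chem state s | gap absent)
    over all unordered neuron pairs, with pair-resampling bootstrap CIs."""
    gap_present, chem_state = _pair_states(gap, chem, subset, gaba)
    if gap_present.sum() == 0:
        raise ValueError("no gap-junction pairs: conditional probabilities undefined")
    lrs, p_gap, p_nogap, n_gap, n_nogap, undefined = _ratios_from(gap_present, chem_state)

    rng = np.random.default_rng(seed)
    n_pairs = len(gap_present)
    boots = {name: [] for name in CHEM_STATES}
    for _ in range(n_boot):
        take = rng.integers(0, n_pairs, size=n_pairs)
        b_lrs, *_ = _ratios_from(gap_present[take], chem_state[take])
        for name in CHEM_STATES:
            boots[name].append(b_lrs[name])
    ci_low, ci_high = {}, {}
    for name in CHEM_STATES:
        vals = np.array(boots[name])
        vals = vals[np.isfinite(vals)]
        if len(vals):
            ci_low[name] = float(np.percentile(vals, 2.5))
            ci_high[name] = float(np.percentile(vals, 97.5))
        else:
            ci_low[name] = ci_high[name] = float("nan")
    return LikelihoodRatios(
        ratios=lrs,
        ci_low=ci_low,
        ci_high=ci_high,
        p_given_gap=p_gap,
        p_given_no_gap=p_nogap,
        n_gap_pairs=n_gap,
        n_no_gap_pairs=n_nogap,
        undefined=undefined,
    )


def degree_correlation_table(
    gap: AdjacencyNetwork,
    chem: AdjacencyNetwork,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[dict]:
    """Pearson correlations between degree sequences with permutation nulls.

    Pairings: gap degree vs chemical in-degree, gap degree vs chemical
    out-degree, chemical in-degree vs out-degree.  The null permutes one
    sequence ``n_perm`` times; its mean and sd are reported.
    """
    if gap.names != chem.names:
        raise ValueError("gap and chem networks must share the same neuron index")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Bg = np.maximum(gap.binary(), gap.binary().T)
    Bc = chem.binary()
    gap_deg = Bg.sum(axis=1)
    in_deg = Bc.sum(axis=0)
    out_deg = Bc.sum(axis=1)
    rng = np.random.default_rng(seed)
    rows = []
    for label, x, y in [
        ("gap/in", gap_deg, in_deg),
        ("gap/out", gap_deg, out_deg),
        ("in/out", in_deg, out_deg),
    ]:
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero-variance degree sequence in pairing {label}")
        r, p = stats.pearsonr(x, y)
        perm_rs = np.empty(n_perm)
        for k in range(n_perm):
            perm_rs[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
        rows.append(
            {
                "pairing": label,
                "r": float(r),
                "p_value": float(p),
                "perm_mean": float(perm_rs.mean()),
                "perm_sd": float(perm_rs.std()),
                "perm_q975": float(np.percentile(perm_rs, 97.5)),
            }
        )
    return rows
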