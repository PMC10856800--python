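"""Module–trait statistics: correlation tests, metabolite/module
significance, GS-vs-MM scatter data and the eigenmetabolite network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, TraitTable
from .modules import Eigenmetabolites, MembershipMatrix, ModuleAssignment, GREY


@dataclass
class ModuleTraitStats:
    """Module × trait correlations with two-sided Student p-values."""

    correlation: pd.DataFrame
    p_value: pd.DataFrame
    n_samples: int
    p_adjusted: pd.DataFrame | None = None


@dataclass
class SignificanceVectors:
    """Per-feature trait correlations (GS), signed and absolute."""

    gs: pd.Series
    trait: str

    @property
    def abs_gs(self) -> pd.Series:
        return self.gs.abs()


@dataclass
class EigengeneNetwork:
    """(modules + traits) correlation matrix with its average-linkage tree."""

    correlation: pd.DataFrame
    linkage_matrix: np.ndarray

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.correlation


def correlation_test_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation under the Student test.

    t = r·sqrt(n−2)/sqrt(1−r²) with n−2 degrees of freedom;
    |r| = 1 returns exactly 0 by convention.
    """
    if n < 3:
        raise ValueError("correlation test requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def _pearson(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector x with each column of Y."""
    x = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((x @ x) * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ Yc) / denom
    return np.clip(r, -1.0, 1.0)


def module_trait_matrix(me: Eigenmetabolites, traits: TraitTable,
                        adjust: bool = False) -> ModuleTraitStats:
    """Correlate each module eigenmetabolite with each trait.

    Samples must be shared and identically ordered.  Raw Student p-values
    by default; ``adjust=True`` adds Benjamini–Hochberg adjusted p-values
    across all cells.
    """
    if list(me.values.index) != traits.sample_ids:
        raise ValueError("ME and trait tables must share identically ordered samples")
    n = me.values.shape[0]
    T = traits.traits.to_numpy(dtype=float)
    const = T.std(axis=0) == 0
    if const.any():
        bad = [t for t, c in zip(traits.trait_names, const) if c]
        raise ValueError(f"constant traits: {bad}")
    M = me.values.to_numpy(dtype=float)
    R = np.empty((M.shape[1], T.shape[1]))
    for j in range(T.shape[1]):
        R[:, j] = _pearson(T[:, j], M)
    P = np.vectorize(lambda r: correlation_test_pvalue(r, n))(R)
    idx, cols = me.module_names, traits.trait_names
    stats_ = ModuleTraitStats(
        pd.DataFrame(R, index=idx, columns=cols),
        pd.DataFrame(P, index=idx, columns=cols), n)
    if adjust:
        flat = stats_.p_value.to_numpy().ravel()
        adj = multipletests(flat, method="fdr_bh")[1].reshape(R.shape)
        stats_.p_adjusted = pd.DataFrame(adj, index=idx, columns=cols)
    return stats_


def metabolite_significance(table: FeatureTable, trait: pd.Series,
                            name: str | None = None) -> SignificanceVectors:
    """GS_i = cor(feature_i, trait) for every feature, signed."""
    X = table.values()
    if np.isnan(X).any():
        raise ValueError("metabolite_significance requires no missing values")
    t = trait.reindex(table.sample_ids).to_numpy(dtype=float)
    gs = _pearson(t, X)
    return SignificanceVectors(pd.Series(gs, index=table.feature_ids),
                               name or str(trait.name))


def module_significance(gs: SignificanceVectors,
                        labels: ModuleAssignment) -> pd.Series:
    """MS per non-grey module: mean |GS| over module members."""
    out = {}
    for module in labels.module_names:
        members = labels.members(module)
        out[module] = float(gs.abs_gs.loc[members].mean())
    return pd.Series(out, name=f"MS_{gs.trait}", dtype=float)


def gs_mm_scatter(gs: SignificanceVectors, mm: MembershipMatrix,
                  labels: ModuleAssignment, module: str,
                  signed_gs: bool = False) -> tuple[pd.DataFrame, float, float]:
    """Per-member (kME, GS) pairs with their Pearson r and Student p.

    By default the scatter uses |GS| against own-module kME; ``signed_gs``
    switches to trait-signed GS.
    """
    if module == GREY or module not in labels.module_names:
        raise ValueError(f"unknown or grey module {module!r}")
    members = labels.members(module)
    if len(members) < 3:
        raise ValueError(f"module {module!r} has fewer than 3 members")
    x = mm.values.loc[members, module]
    y = gs.gs.loc[members] if signed_gs else gs.abs_gs.loc[members]
    data = pd.DataFrame({"kme": x, "gs": y})
    r = float(np.corrcoef(x, y)[0, 1])
    p = correlation_test_pvalue(r, len(members))
    return data, r, p


def eigengene_network(me: Eigenmetabolites, traits: TraitTable | None = None,
                      include_traits: list[str] | None = None) -> EigengeneNetwork:
    """Correlation network over MEs with selected traits interposed.

    Average-linkage clustering on 1 − cor groups modules (and traits) into
    meta-modules; a trait lands next to the modules tracking it.
    """
    blocks = [me.values]
    if traits is not None and include_traits:
        blocks.append(traits.traits[include_traits])
    combined = pd.concat(blocks, axis=1)
    C = np.corrcoef(combined.to_numpy(dtype=float), rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    names = list(combined.columns)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    lm = linkage(squareform(D, checks=False), method="average")
    return EigengeneNetwork(pd.DataFrame(C, index=names, columns=names), lm)
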