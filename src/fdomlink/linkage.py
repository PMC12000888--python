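"""DOM–bacteria linkage statistics.

Two analyses: (1) Spearman correlation maps between taxon relative abundances
(aggregated at a taxonomic rank) and DOM component/index values, with BH
correction within the table; (2) a Mantel-style permutation test relating
pairwise |βNTI| to the pairwise Euclidean distance of each FDOM component's
per-sample values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_qvalues, spearman_rho_p
from .assembly import BetaNTIResult
from .community import FeatureTable
from .errors import FdomlinkError, UndefinedDistanceError

__all__ = [
    "LinkageTable",
    "MantelResult",
    "aggregate_taxa",
    "spearman_map",
    "bnti_fdom_correlation",
]


@dataclass
class LinkageTable:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for taxon in self.rho.index:
            for var in self.rho.columns:
                rows.append({"taxon": taxon, "variable": var,
                             "rho": self.rho.at[taxon, var],
                             "p": self.p.at[taxon, var],
                             "q": self.q.at[taxon, var]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MantelResult:
    component: str
    rho: float
    p_perm: float
    p_naive: float  # treats pairs as independent; anti-conservative
    n_permutations: int
    seed: int | None


def aggregate_taxa(table: FeatureTable, rank: str) -> pd.DataFrame:
    """Sum counts by rank label, then convert to per-sample relative abundance.

    ASVs without taxonomy coverage at ``rank`` fall into ``Unassigned``.
    Returns a (taxa × samples) DataFrame whose columns sum to 1.
    """
    if table.taxonomy is None:
        raise FdomlinkError("feature table has no taxonomy")
    if rank not in table.taxonomy.columns:
        raise FdomlinkError(f"rank {rank!r} absent from taxonomy "
                            f"(have {list(table.taxonomy.columns)})")
    labels = []
    for asv in table.asv_ids:
        if asv in table.taxonomy.index:
            val = table.taxonomy.at[asv, rank]
            labels.append(str(val) if pd.notna(val) and str(val) else "Unassigned")
        else:
            labels.append("Unassigned")
    df = pd.DataFrame(table.counts, index=pd.Index(labels, name=rank),
                      columns=table.sample_ids)
    agg = df.groupby(level=0).sum()
    totals = agg.sum(axis=0)
    if (totals <= 0).any():
        raise UndefinedDistanceError("all-zero sample in aggregation")
    return agg / totals


def spearman_map(taxa: pd.DataFrame, dom: pd.DataFrame) -> LinkageTable:
    """Spearman rho/p/q for every (taxon, DOM variable) pair.

    Both inputs are (variables × samples); columns are aligned on their shared
    sample ids (at least 5 required).
    """
    shared = [s for s in taxa.columns if s in set(dom.columns)]
    if len(shared) < 5:
        raise FdomlinkError(f"need >= 5 shared samples, got {len(shared)}")
    tx = taxa[shared]
    dm = dom[shared]
    rho = pd.DataFrame(index=tx.index, columns=dm.index, dtype=float)
    pmat = pd.DataFrame(index=tx.index, columns=dm.index, dtype=float)
    for taxon in tx.index:
        for var in dm.index:
            r, p = spearman_rho_p(tx.loc[taxon].to_numpy(dtype=float),
                                  dm.loc[var].to_numpy(dtype=float))
            rho.at[taxon, var] = r
            pmat.at[taxon, var] = p
    q = pd.DataFrame(
        bh_qvalues(pmat.to_numpy().ravel()).reshape(pmat.shape),
        index=pmat.index, columns=pmat.columns,
    )
    return LinkageTable(rho=rho, p=pmat, q=q)


def _mantel(a_condensed: np.ndarray, b_square: np.ndarray, n_perm: int,
            rng: np.random.Generator) -> tuple[float, float]:
    n = b_square.shape[0]
    iu = np.triu_indices(n, 1)
    rank_a = sps.rankdata(a_condensed)
    rank_a_c = rank_a - rank_a.mean()
    norm_a = np.sqrt(rank_a_c @ rank_a_c)

    def rho_of(b_sq: np.ndarray) -> float:
        bv = sps.rankdata(b_sq[iu])
        bc = bv - bv.mean()
        nb = np.sqrt(bc @ bc)
        if norm_a == 0 or nb == 0:
            raise UndefinedDistanceError("zero-variance distance matrix")
        return float((rank_a_c @ bc) / (norm_a * nb))

    rho_obs = rho_of(b_square)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(rho_of(b_square[np.ix_(perm, perm)])) >= abs(rho_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return rho_obs, p


def bnti_fdom_correlation(bnti: BetaNTIResult | np.ndarray, dom: pd.DataFrame,
                          n_perm: int = 999, seed: int = 0,
                          sample_ids: list[str] | None = None) -> list[MantelResult]:
    """Spearman correlation of |βNTI| with per-component FDOM distances.

    For each DOM component the pairwise distance is the 1-D Euclidean distance
    |v_i − v_j| of its per-sample values. Significance comes from a Mantel
    permutation of one matrix's sample labels:
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)``. A naive p-value
    treating the pairs as independent is also reported for comparison.
    """
    if isinstance(bnti, BetaNTIResult):
        bnti_mat = np.abs(bnti.bnti)
        ids = bnti.sample_ids
    else:
        bnti_mat = np.abs(np.asarray(bnti, dtype=float))
        ids = sample_ids or [str(i) for i in range(bnti_mat.shape[0])]
    missing = [s for s in ids if s not in set(dom.columns)]
    if missing:
        raise FdomlinkError(f"DOM table missing samples {missing[:5]}")
    n = len(ids)
    if n < 5:
        raise FdomlinkError("need >= 5 samples")
    dom = dom[ids]
    iu = np.triu_indices(n, 1)
    a = bnti_mat[iu]
    if not np.all(np.isfinite(a)):
        keep = np.isfinite(bnti_mat[iu])
        if keep.sum() < 5:
            raise FdomlinkError("too few finite βNTI pairs")
        # undefined pairs are dropped from the correlation
        a = a[keep]
    else:
        keep = None

    results = []
    for comp in dom.index:
        v = dom.loc[comp].to_numpy(dtype=float)
        d_sq = np.abs(v[:, None] - v[None, :])
        if np.ptp(d_sq[iu]) == 0:
            raise UndefinedDistanceError(
                f"component {comp!r} is constant across samples")
        comp_key = zlib.crc32(str(comp).encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, comp_key]))
        if keep is None:
            rho_obs, p_perm = _mantel(a, d_sq, n_perm, rng)
        else:
            # with undefined pairs, permute then subset to the finite pairs
            rank_a = sps.rankdata(a)

            def rho_sub(mat):
                bv = sps.rankdata(mat[iu][keep])
                ra = rank_a - rank_a.mean()
                rb = bv - bv.mean()
                den = np.sqrt((ra @ ra) * (rb @ rb))
                if den == 0:
                    raise UndefinedDistanceError("zero-variance distance matrix")
                return float((ra @ rb) / den)

            rho_obs = rho_sub(d_sq)
            exceed = sum(
                abs(rho_sub(d_sq[np.ix_(p_, p_)])) >= abs(rho_obs) - 1e-12
                for p_ in (rng.permutation(n) for _ in range(n_perm))
            )
            p_perm = (1 + exceed) / (1 + n_perm)
        _, p_naive = spearman_rho_p(a, d_sq[iu] if keep is None else d_sq[iu][keep])
        results.append(MantelResult(component=str(comp), rho=rho_obs,
                                    p_perm=p_perm, p_naive=p_naive,
                                    n_permutations=n_perm, seed=seed))
    return results
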