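"""Feature-table handling, α-diversity, dissimilarity, ordination, group tests."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateFitError,
    FdomlinkError,
    FormatError,
    UndefinedDistanceError,
    UndefinedDiversityError,
)

__all__ = [
    "FeatureTable",
    "AlphaDiversity",
    "chao1",
    "shannon",
    "simpson",
    "pielou",
    "alpha_diversity",
    "bray_curtis",
    "nmds",
    "NMDSResult",
    "group_compare",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class FeatureTable:
    """ASV × sample count table with optional taxonomy.

    ``counts`` has ASVs in rows and samples in columns; entries are
    nonnegative integers. ``taxonomy`` maps a subset of ``asv_ids`` to rank
    labels (columns named after :data:`RANKS` entries).
    """

    counts: np.ndarray
    asv_ids: list[str]
    sample_ids: list[str]
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D (ASVs × samples) matrix")
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs × {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise FormatError("negative counts")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise FormatError("duplicate ASV ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy.index) - set(self.asv_ids)
            if unknown:
                raise FormatError(f"taxonomy covers unknown ASVs: {sorted(unknown)[:5]}")

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        totals = self.counts.sum(axis=0).astype(float)
        if np.any(totals <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
            raise UndefinedDiversityError(f"all-zero samples: {bad}")
        return self.counts / totals

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(self.counts[:, idx], list(self.asv_ids),
                            list(sample_ids), self.taxonomy)

    def subsample(self, depth: int, seed: int = 0) -> "FeatureTable":
        """Rarefy every sample to ``depth`` reads without replacement."""
        totals = self.counts.sum(axis=0)
        if np.any(totals < depth):
            bad = [self.sample_ids[i] for i in np.nonzero(totals < depth)[0]]
            raise FdomlinkError(f"samples below depth {depth}: {bad}")
        rng = np.random.default_rng(seed)
        out = np.zeros_like(self.counts)
        for j in range(self.n_samples):
            pool = np.repeat(np.arange(self.n_asvs), self.counts[:, j])
            chosen = rng.choice(pool, size=depth, replace=False)
            out[:, j] = np.bincount(chosen, minlength=self.n_asvs)
        return FeatureTable(out, list(self.asv_ids), list(self.sample_ids), self.taxonomy)

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, taxonomy_path=None) -> "FeatureTable":
        """Read an ASVs-in-rows TSV; optional taxonomy TSV (asv_id + ranks or
        a single semicolon-delimited ``taxonomy`` column)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise FormatError(f"no sample columns in {path}")
        counts = df.to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise FormatError(f"non-numeric counts in {path}")
        taxonomy = load_taxonomy_tsv(taxonomy_path) if taxonomy_path else None
        return cls(counts.astype(np.int64), list(df.index.astype(str)),
                   list(df.columns.astype(str)), taxonomy)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=self.asv_ids, columns=self.sample_ids)
        df.index.name = "asv_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_biom_json(cls, path) -> "FeatureTable":
        """Read a BIOM v1 (JSON) table."""
        doc = json.loads(Path(path).read_text())
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        counts = np.zeros((len(asv_ids), len(sample_ids)))
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                counts[int(r), int(c)] = v
        else:
            counts[:] = np.asarray(doc["data"])
        tax_rows = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            if "taxonomy" in md:
                tax_rows[r["id"]] = _parse_lineage(";".join(md["taxonomy"]))
        taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index") if tax_rows else None
        return cls(counts.astype(np.int64), asv_ids, sample_ids, taxonomy)


def _parse_lineage(lineage: str) -> dict:
    parts = [p.strip() for p in lineage.split(";")]
    out = {}
    for rank, part in zip(RANKS, parts):
        if "__" in part:
            part = part.split("__", 1)[1]
        if part:
            out[rank] = part
    return out


def load_taxonomy_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [c.lower() for c in df.columns]
    if "taxonomy" in df.columns and not set(RANKS) & set(df.columns):
        return pd.DataFrame.from_dict(
            {i: _parse_lineage(s) for i, s in df["taxonomy"].items()}, orient="index"
        )
    return df


# ---- α diversity ---------------------------------------------------------


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    chao1: float
    shannon: float
    simpson: float
    pielou: float


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or np.any(c < 0):
        raise UndefinedDiversityError("counts must be a nonnegative 1-D vector")
    if c.sum() <= 0:
        raise UndefinedDiversityError("diversity undefined for an all-zero vector")
    return c


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1²/(2·F2), bias-corrected when F2 = 0."""
    c = _check_counts(counts)
    if not np.all(c == np.floor(c)):
        raise UndefinedDiversityError("chao1 requires integer counts")
    s_obs = int(np.sum(c > 0))
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy H = −Σ p·log_base p over taxa with p > 0."""
    c = _check_counts(counts)
    p = c[c > 0] / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def simpson(counts) -> float:
    """Gini–Simpson index 1 − Σ p²."""
    c = _check_counts(counts)
    p = c / c.sum()
    return float(1.0 - (p * p).sum())


def pielou(counts, base: float = 2.0) -> float:
    """Pielou evenness J = H / log_base(S_obs)."""
    c = _check_counts(counts)
    s_obs = int(np.sum(c > 0))
    if s_obs < 2:
        raise UndefinedDiversityError("pielou undefined for a single observed taxon")
    return shannon(c, base=base) / (np.log(s_obs) / np.log(base))


def alpha_diversity(table: FeatureTable, base: float = 2.0) -> pd.DataFrame:
    rows = []
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        s_obs = int(np.sum(c > 0))
        rows.append({
            "sample_id": sid,
            "chao1": chao1(c),
            "shannon": shannon(c, base=base),
            "simpson": simpson(c),
            "pielou": pielou(c, base=base) if s_obs > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---- β diversity & ordination -------------------------------------------


def bray_curtis(table: FeatureTable) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity, BC(i,j) = Σ|x−y| / Σ(x+y)."""
    x = table.counts.astype(float)
    n = table.n_samples
    if n < 2:
        raise UndefinedDistanceError("need at least 2 samples")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[:, i] + x[:, j]).sum()
            if denom == 0:
                raise UndefinedDistanceError(
                    f"distance undefined between all-zero samples "
                    f"{table.sample_ids[i]!r} and {table.sample_ids[j]!r}"
                )
            d[i, j] = d[j, i] = np.abs(x[:, i] - x[:, j]).sum() / denom
    return d


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    stress_history: np.ndarray
    seed: int | None = None

    def __iter__(self):
        return iter((self.coordinates, self.stress))


def _isotonic(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pool-adjacent-violators: nondecreasing least-squares fit to y."""
    n = y.size
    sol = y.astype(float).copy()
    w = np.ones(n) if weights is None else weights.astype(float).copy()
    # blocks as (value, weight, count) stacks
    vals, wts, cnts = [], [], []
    for i in range(n):
        vals.append(sol[i])
        wts.append(w[i])
        cnts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wt = wts[-2] + wts[-1]
            ct = cnts[-2] + cnts[-1]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [wt]
            cnts = cnts[:-2] + [ct]
    out = np.empty(n)
    pos = 0
    for v, ct in zip(vals, cnts):
        out[pos:pos + ct] = v
        pos += ct
    return out


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = np.sum(d_config ** 2)
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((d_config - disparities) ** 2) / denom))


def nmds(dist: np.ndarray, k: int = 2, n_starts: int = 4, max_iter: int = 300,
         seed: int = 0, tol: float = 1e-7) -> NMDSResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Iterative majorization (Guttman transform) alternated with monotone
    regression of configuration distances on the input dissimilarity order;
    best of ``n_starts`` (the first start is the classical-scaling solution,
    the rest are random). Deterministic given ``seed``.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise FdomlinkError("dist must be a symmetric square matrix")
    if k >= n:
        raise FdomlinkError(f"embedding dimension k={k} must be < n={n}")
    iu = np.triu_indices(n, 1)
    delta = d[iu]
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    # classical scaling start
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(bmat)
    idx = np.argsort(evals)[::-1][:k]
    classical = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))

    best: NMDSResult | None = None
    for start in range(n_starts):
        x = classical.copy() if start == 0 else rng.normal(size=(n, k))
        history = []
        prev_stress = np.inf
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dx = np.sqrt((diff ** 2).sum(-1))
            dvec = dx[iu]
            disp = np.empty_like(dvec)
            disp[order] = _isotonic(dvec[order])
            stress = _stress1(dvec, disp)
            if stress > prev_stress + 1e-15:
                break  # keep the best configuration seen in this start
            history.append(stress)
            if prev_stress - stress < tol:
                prev_stress = stress
                x_best = x
                break
            prev_stress = stress
            x_best = x
            # Guttman transform with disparities
            dhat = np.zeros((n, n))
            dhat[iu] = disp
            dhat = dhat + dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dx > 0, dhat / dx, 0.0)
            bmat_g = -ratio
            np.fill_diagonal(bmat_g, ratio.sum(axis=1))
            x = bmat_g @ x / n
        result = NMDSResult(coordinates=x_best, stress=prev_stress,
                            stress_history=np.asarray(history), seed=seed)
        if best is None or result.stress < best.stress:
            best = result
    return best


# ---- group comparison ----------------------------------------------------


def group_compare(values, groups, test: str = "welch_t") -> tuple[float, float]:
    """Compare a per-sample variable between groups.

    ``welch_t`` and ``mann_whitney`` require exactly two groups; ``anova``
    accepts two or more. Returns (statistic, two-sided p). Degenerate input
    with zero variance and equal group means yields (0.0, 1.0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    samples = [values[groups == g] for g in labels]
    if test in {"welch_t", "mann_whitney"} and len(labels) != 2:
        raise DegenerateFitError(f"{test} requires exactly 2 groups, got {len(labels)}")
    if test in {"welch_t", "anova"} and any(len(s) < 2 for s in samples):
        raise DegenerateFitError("each group needs at least 2 members")
    if len(labels) < 2:
        raise DegenerateFitError("need at least 2 groups")
    if all(np.ptp(s) == 0 for s in samples) and len({float(s[0]) for s in samples}) == 1:
        return 0.0, 1.0
    if test == "welch_t":
        stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=False)
    elif test == "mann_whitney":
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif test == "anova":
        stat, p = sps.f_oneway(*samples)
    else:
        raise DegenerateFitError(f"unknown test {test!r}")
    return float(stat), float(p)
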