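"""Nonnegative PARAFAC decomposition of EEM stacks.

The trilinear model approximates the sample × emission × excitation tensor as
a sum of K rank-one components ``score ⊗ em_loading ⊗ ex_loading`` with all
three factor matrices constrained nonnegative. Fitting uses hierarchical
alternating least squares (HALS) with an EM step for missing (NaN) cells, so
the observed-data loss is monotone non-increasing across iterations. Loadings
are reported in the unit-maximum convention: every loading column has maximum
exactly 1 and the sample scores absorb all intensity scale, which makes the
scores directly interpretable as Fmax values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eem import EEMDataset
from .errors import FdomlinkError, RankError, UndefinedIndexError, ValidationError

__all__ = [
    "ParafacModel",
    "ComponentFingerprint",
    "SplitHalfReport",
    "fit_parafac",
    "model_order_scan",
    "split_half_validate",
    "tucker_congruence",
    "core_consistency",
    "fmax_scores",
    "percent_composition",
    "classify_component",
    "component_fingerprints",
    "match_reference",
    "match_components",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class ParafacModel:
    n_components: int
    ex_loadings: np.ndarray          # (n_ex, K), unit-maximum columns
    em_loadings: np.ndarray          # (n_em, K), unit-maximum columns
    scores: np.ndarray               # (n_samples, K), nonnegative
    explained_variance: float
    sse: float
    n_iterations: int
    converged: bool
    seed: int | None
    ex_nm: np.ndarray | None = None
    em_nm: np.ndarray | None = None
    sample_ids: list[str] | None = None
    loss_history: np.ndarray | None = None
    _internal_factors: tuple | None = field(default=None, repr=False)


@dataclass(frozen=True)
class ComponentFingerprint:
    component: int
    ex_peak_nm: float
    em_peak_nm: float
    label: str


@dataclass
class SplitHalfReport:
    n_splits: int
    threshold: float
    records: pd.DataFrame  # columns: split, component, ex_congruence, em_congruence
    passed: bool

    @property
    def min_congruence(self) -> float:
        return float(self.records[["ex_congruence", "em_congruence"]].min().min())


def tucker_congruence(a, b) -> float:
    """Tucker's congruence coefficient: Σab / sqrt(Σa²·Σb²), in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise FdomlinkError("congruence requires equal-length vectors")
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0 or nb == 0:
        raise FdomlinkError("congruence undefined for a zero vector")
    return float((a @ b) / (na * nb))


def _hals_update(factor: np.ndarray, gram: np.ndarray, proj: np.ndarray,
                 rng: np.random.Generator) -> None:
    """In-place nonnegative HALS sweep over the columns of one factor."""
    k_total = factor.shape[1]
    for k in range(k_total):
        g_kk = gram[k, k]
        if g_kk < _EPS:
            continue
        col = factor[:, k] + (proj[:, k] - factor @ gram[:, k]) / g_kk
        np.maximum(col, 0.0, out=col)
        if not col.any():
            # collapsed component: restart with a small random nonnegative draw
            col = rng.uniform(0.1, 1.0, size=col.shape) * 1e-6
        factor[:, k] = col


def _als_missing(x: np.ndarray, k: int, init: tuple, max_iter: int, tol: float,
                 rng: np.random.Generator, inner_sweeps: int = 3):
    """HALS-ALS on a (samples, em, ex) tensor with NaN treated as missing (EM fill)."""
    mask = np.isfinite(x)
    any_missing = not mask.all()
    x_obs = np.where(mask, x, 0.0)
    total_ss = float(np.sum(x_obs[mask] ** 2))
    a, b, c = (f.copy() for f in init)
    if any_missing:
        # EM fill with the initial model so the observed loss is monotone
        xf = np.where(mask, x_obs, np.einsum("ik,jk,lk->ijl", a, b, c))
    else:
        xf = x_obs
    history = []
    sse_prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for _ in range(inner_sweeps):
            gb, gc = b.T @ b, c.T @ c
            _hals_update(a, gb * gc, np.einsum("ijl,jk,lk->ik", xf, b, c), rng)
            ga = a.T @ a
            _hals_update(b, ga * gc, np.einsum("ijl,ik,lk->jk", xf, a, c), rng)
            gb = b.T @ b
            proj_c = np.einsum("ijl,ik,jk->lk", xf, a, b)
            _hals_update(c, ga * gb, proj_c, rng)
        if any_missing:
            model = np.einsum("ik,jk,lk->ijl", a, b, c)
            xf = np.where(mask, x_obs, model)
            sse = float(np.sum((x_obs - model)[mask] ** 2))
        else:
            # ||X - M||² from Gram matrices, avoiding the full model tensor
            proj_c = np.einsum("ijl,ik,jk->lk", xf, a, b)
            cross = float(np.sum(proj_c * c))
            model_ss = float(np.sum((a.T @ a) * (b.T @ b) * (c.T @ c)))
            sse = max(total_ss - 2.0 * cross + model_ss, 0.0)
        history.append(sse)
        if np.isfinite(sse_prev) and sse_prev - sse <= tol * max(sse_prev, _EPS):
            converged = True
            break
        sse_prev = sse
    return a, b, c, history[-1], it, converged, np.asarray(history), total_ss


def _svd_init(x_obs: np.ndarray, k: int, rng: np.random.Generator) -> tuple:
    """Deterministic start: absolute leading singular vectors of each unfolding."""
    factors = []
    n_i, n_j, n_l = x_obs.shape
    for mode, dim in ((0, n_i), (1, n_j), (2, n_l)):
        unfold = np.moveaxis(x_obs, mode, 0).reshape(dim, -1)
        kk = min(k, min(unfold.shape))
        u, _, _ = np.linalg.svd(unfold, full_matrices=False)
        f = np.abs(u[:, :kk])
        if kk < k:
            f = np.hstack([f, rng.uniform(0.1, 1.0, (dim, k - kk))])
        factors.append(f + 1e-3)
    return tuple(factors)


def _normalize_convention(a, b, c):
    """Scale loading columns to unit maximum, pushing scale into the scores."""
    b = b.copy()
    c = c.copy()
    a = a.copy()
    for k in range(a.shape[1]):
        mb = b[:, k].max()
        mc = c[:, k].max()
        if mb > 0:
            b[:, k] /= mb
        if mc > 0:
            c[:, k] /= mc
        a[:, k] *= mb * mc
    return a, b, c


def _as_tensor(ds) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, list | None]:
    if isinstance(ds, EEMDataset):
        return ds.tensor(), ds.ex_nm, ds.em_nm, ds.sample_ids
    x = np.asarray(ds, dtype=float)
    if x.ndim != 3:
        raise FdomlinkError("expected an EEMDataset or a 3-D (samples, em, ex) array")
    return x, None, None, None


def fit_parafac(ds, k: int, n_starts: int = 5, max_iter: int = 2500,
                tol: float = 1e-8, seed: int = 0, *,
                normalize_samples: bool = True, floor_negative: bool = False,
                init_factors: tuple | None = None) -> ParafacModel:
    """Fit a K-component nonnegative PARAFAC model to an EEM stack.

    Runs ``n_starts`` seeded random initializations (plus ``init_factors`` as a
    warm start, if given) and keeps the lowest-SSE solution. NaN cells are
    excluded from both the factor updates and the reported loss. With
    ``normalize_samples`` each sample slab is scaled to unit sum of squares
    during fitting to balance leverage; scores are rescaled back afterwards.
    """
    x, ex_nm, em_nm, sample_ids = _as_tensor(ds)
    n_samples, n_em, n_ex = x.shape
    if k < 1:
        raise RankError("K must be >= 1")
    if k > min(n_samples, n_em, n_ex):
        raise RankError(f"K={k} exceeds the smallest tensor dimension {min(x.shape)}")
    if n_samples < k:
        raise RankError(f"need at least K={k} samples, got {n_samples}")
    if floor_negative:
        x = np.where(np.isfinite(x), np.maximum(x, 0.0), x)

    scale = np.ones(n_samples)
    if normalize_samples:
        for i in range(n_samples):
            slab = x[i]
            ss = np.nansum(slab ** 2)
            if ss > 0:
                scale[i] = np.sqrt(ss)
        x = x / scale[:, None, None]

    mask = np.isfinite(x)
    x_obs = np.where(mask, x, 0.0)
    total_ss_norm = float(np.sum(x_obs[mask] ** 2))

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_starts + 2)
    inits = []
    if init_factors is not None:
        inits.append((tuple(np.asarray(f, dtype=float) for f in init_factors),
                      np.random.default_rng(child_seeds[-1])))
    svd_rng = np.random.default_rng(child_seeds[-2])
    inits.append((_svd_init(x_obs, k, svd_rng), svd_rng))
    for cs in child_seeds[:n_starts]:
        rng = np.random.default_rng(cs)
        inits.append(((rng.uniform(0.1, 1.0, (n_samples, k)),
                       rng.uniform(0.1, 1.0, (n_em, k)),
                       rng.uniform(0.1, 1.0, (n_ex, k))), rng))

    # run every start briefly, then polish only the best to convergence
    burn_in = min(100, max_iter)
    best = best_rng = None
    for init, rng in inits:
        result = _als_missing(x, k, init, burn_in, tol, rng)
        if best is None or result[3] < best[3]:
            best, best_rng = result, rng
    a, b, c, sse_norm, n_iter, converged, history, _ = best
    if not converged and max_iter > burn_in:
        result = _als_missing(x, k, (a, b, c), max_iter - burn_in, tol, best_rng)
        a, b, c, sse_norm, extra_iter, converged, more_history, _ = result
        n_iter += extra_iter
        history = np.concatenate([history, more_history])

    # deterministic component order: by descending total score magnitude
    a, b, c = _normalize_convention(a, b, c)
    order = np.argsort(-a.sum(axis=0), kind="stable")
    a, b, c = a[:, order], b[:, order], c[:, order]

    scores = a * scale[:, None]
    # SSE / explained variance on the original (unnormalized) scale
    model_t = np.einsum("ik,jk,lk->ijl", scores, b, c)
    x_orig = x * scale[:, None, None]
    sse = float(np.sum((np.where(mask, x_orig, 0.0) - model_t)[mask] ** 2))
    total_ss = float(np.sum(x_orig[mask] ** 2))
    ev = 1.0 - sse / total_ss if total_ss > 0 else 0.0

    return ParafacModel(
        n_components=k,
        ex_loadings=c,
        em_loadings=b,
        scores=scores,
        explained_variance=ev,
        sse=sse,
        n_iterations=n_iter,
        converged=converged,
        seed=seed,
        ex_nm=ex_nm,
        em_nm=em_nm,
        sample_ids=sample_ids,
        loss_history=history,
        _internal_factors=(a, b, c),
    )


def core_consistency(ds, model: ParafacModel) -> float:
    """CORCONDIA: how close the least-squares Tucker core is to superdiagonal.

    Missing cells are filled with the model prediction before the core is
    estimated. 100 means perfectly trilinear; values well below ~50 indicate
    an over-factored model.
    """
    x, _, _, _ = _as_tensor(ds)
    a, b, c = model.scores, model.em_loadings, model.ex_loadings
    pred = np.einsum("ik,jk,lk->ijl", a, b, c)
    xf = np.where(np.isfinite(x), x, pred)
    pa, pb, pc = (np.linalg.pinv(m) for m in (a, b, c))
    g = np.einsum("ri,ijl->rjl", pa, xf)
    g = np.einsum("sj,rjl->rsl", pb, g)
    g = np.einsum("tl,rsl->rst", pc, g)
    k = model.n_components
    t = np.zeros((k, k, k))
    for i in range(k):
        t[i, i, i] = 1.0
    return float(100.0 * (1.0 - np.sum((g - t) ** 2) / k))


def model_order_scan(ds, k_range=range(4, 9), n_starts: int = 5,
                     max_iter: int = 2500, tol: float = 1e-8,
                     seed: int = 0, **fit_kw) -> pd.DataFrame:
    """Fit one model per K and tabulate fit diagnostics.

    Each K beyond the first additionally warm-starts from the previous best
    solution padded with one small random component, which makes explained
    variance non-decreasing in K up to ALS tolerance.
    """
    ks = sorted(k_range)
    if not ks:
        raise FdomlinkError("empty K range")
    rows = []
    prev = None
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for k in ks:
        init = None
        if prev is not None and prev._internal_factors is not None:
            pa, pb, pc = prev._internal_factors
            pad = k - pa.shape[1]
            if pad > 0:
                init = (
                    np.hstack([pa, rng.uniform(0.1, 1.0, (pa.shape[0], pad)) * 1e-8]),
                    np.hstack([pb, rng.uniform(0.1, 1.0, (pb.shape[0], pad)) * 1e-8]),
                    np.hstack([pc, rng.uniform(0.1, 1.0, (pc.shape[0], pad)) * 1e-8]),
                )
        try:
            model = fit_parafac(ds, k, n_starts=n_starts, max_iter=max_iter,
                                tol=tol, seed=seed, init_factors=init, **fit_kw)
        except FdomlinkError as exc:
            raise type(exc)(f"K={k}: {exc}") from exc
        rows.append({
            "K": k,
            "explained_variance": model.explained_variance,
            "core_consistency": core_consistency(ds, model),
            "sse": model.sse,
            "converged": model.converged,
        })
        prev = model
    return pd.DataFrame(rows)


def match_components(em_a, ex_a, em_b, ex_b) -> list[tuple[int, int, float, float]]:
    """Greedy matching of components across two fits by congruence product.

    Returns ``(idx_a, idx_b, ex_congruence, em_congruence)`` per match; ties
    resolved by component index.
    """
    ka, kb = em_a.shape[1], em_b.shape[1]
    prod = np.zeros((ka, kb))
    exc = np.zeros((ka, kb))
    emc = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            exc[i, j] = tucker_congruence(ex_a[:, i], ex_b[:, j])
            emc[i, j] = tucker_congruence(em_a[:, i], em_b[:, j])
            prod[i, j] = exc[i, j] * emc[i, j]
    matches = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    flat = sorted(
        ((prod[i, j], i, j) for i in range(ka) for j in range(kb)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for _, i, j in flat:
        if i in used_a or j in used_b:
            continue
        matches.append((i, j, exc[i, j], emc[i, j]))
        used_a.add(i)
        used_b.add(j)
        if len(matches) == min(ka, kb):
            break
    return matches


def split_half_validate(ds, k: int, n_splits: int = 2, threshold: float = 0.95,
                        seed: int = 0, n_starts: int = 3, max_iter: int = 2500,
                        tol: float = 1e-8, **fit_kw) -> SplitHalfReport:
    """Split-half validation: fit independent halves and compare loadings."""
    x, _, _, _ = _as_tensor(ds)
    n = x.shape[0]
    if n < 2 * k:
        raise ValidationError(f"split-half needs >= {2 * k} samples, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(n)
        half_a, half_b = np.sort(perm[: n // 2]), np.sort(perm[n // 2:])
        seed_a, seed_b = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
        ma = fit_parafac(x[half_a], k, n_starts=n_starts, max_iter=max_iter,
                         tol=tol, seed=seed_a, **fit_kw)
        mb = fit_parafac(x[half_b], k, n_starts=n_starts, max_iter=max_iter,
                         tol=tol, seed=seed_b, **fit_kw)
        for i, j, c_ex, c_em in match_components(ma.em_loadings, ma.ex_loadings,
                                                 mb.em_loadings, mb.ex_loadings):
            rows.append({"split": split, "component_a": i, "component_b": j,
                         "ex_congruence": c_ex, "em_congruence": c_em})
    records = pd.DataFrame(rows)
    passed = bool((records[["ex_congruence", "em_congruence"]] >= threshold).all().all())
    return SplitHalfReport(n_splits=n_splits, threshold=threshold,
                           records=records, passed=passed)


def fmax_scores(model: ParafacModel) -> np.ndarray:
    """Fmax per sample and component: score × max(ex loading) × max(em loading)."""
    return model.scores * model.ex_loadings.max(axis=0) * model.em_loadings.max(axis=0)


def percent_composition(fmax: np.ndarray) -> np.ndarray:
    """Per-sample percentages of each component; rows sum to 100."""
    fmax = np.asarray(fmax, dtype=float)
    if np.any(fmax < 0):
        raise FdomlinkError("Fmax values must be nonnegative")
    sums = fmax.sum(axis=1)
    if np.any(sums <= 0):
        bad = np.nonzero(sums <= 0)[0].tolist()
        raise UndefinedIndexError(f"composition undefined for zero-Fmax rows {bad}")
    return fmax / sums[:, None] * 100.0


DEFAULT_CLASSIFICATION_RULES = {
    "tyrosine_em_max": 320.0,
    "tryptophan_em_max": 380.0,
    "terrestrial_ex_max": 260.0,
}


def classify_component(ex_peak_nm: float, em_peak_nm: float,
                       rules: dict | None = None) -> str:
    """Peak-position classification of a fluorophore component."""
    r = {**DEFAULT_CLASSIFICATION_RULES, **(rules or {})}
    if not (np.isfinite(ex_peak_nm) and np.isfinite(em_peak_nm)):
        return "unclassified"
    if em_peak_nm < r["tyrosine_em_max"]:
        return "tyrosine-like"
    if em_peak_nm < r["tryptophan_em_max"]:
        return "tryptophan-like"
    if ex_peak_nm < r["terrestrial_ex_max"]:
        return "terrestrial humic-like"
    return "microbial humic-like"


def component_fingerprints(model: ParafacModel,
                           rules: dict | None = None) -> list[ComponentFingerprint]:
    if model.ex_nm is None or model.em_nm is None:
        raise FdomlinkError("model carries no wavelength grid")
    out = []
    for k in range(model.n_components):
        ex_peak = float(model.ex_nm[int(np.argmax(model.ex_loadings[:, k]))])
        em_peak = float(model.em_nm[int(np.argmax(model.em_loadings[:, k]))])
        out.append(ComponentFingerprint(
            component=k,
            ex_peak_nm=ex_peak,
            em_peak_nm=em_peak,
            label=classify_component(ex_peak, em_peak, rules),
        ))
    return out


def match_reference(model: ParafacModel, library: list[dict]) -> pd.DataFrame:
    """Match each model component against a local reference spectrum library.

    Library entries are dicts with keys ``label``, ``ex_nm``, ``ex_loading``,
    ``em_nm``, ``em_loading``; spectra are resampled to the model grid before
    the congruence product is computed.
    """
    if not library:
        raise FdomlinkError("empty reference library")
    if model.ex_nm is None or model.em_nm is None:
        raise FdomlinkError("model carries no wavelength grid")
    rows = []
    for k in range(model.n_components):
        best_label, best_score, best_ex, best_em = None, -np.inf, np.nan, np.nan
        for entry in library:
            ex_ref = np.interp(model.ex_nm, np.asarray(entry["ex_nm"], dtype=float),
                               np.asarray(entry["ex_loading"], dtype=float))
            em_ref = np.interp(model.em_nm, np.asarray(entry["em_nm"], dtype=float),
                               np.asarray(entry["em_loading"], dtype=float))
            c_ex = tucker_congruence(model.ex_loadings[:, k], ex_ref)
            c_em = tucker_congruence(model.em_loadings[:, k], em_ref)
            score = c_ex * c_em
            if score > best_score:
                best_label, best_score = entry["label"], score
                best_ex, best_em = c_ex, c_em
        rows.append({"component": k, "best_match": best_label,
                     "congruence": best_score, "ex_congruence": best_ex,
                     "em_congruence": best_em})
    return pd.DataFrame(rows)


def save_model(model: ParafacModel, outdir) -> None:
    """Serialize a model to a directory of CSVs plus a JSON diagnostics file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"C{k + 1}" for k in range(model.n_components)]
    ex_idx = model.ex_nm if model.ex_nm is not None else np.arange(model.ex_loadings.shape[0])
    em_idx = model.em_nm if model.em_nm is not None else np.arange(model.em_loadings.shape[0])
    ids = model.sample_ids if model.sample_ids is not None else \
        [f"S{i}" for i in range(model.scores.shape[0])]
    pd.DataFrame(model.ex_loadings, index=ex_idx, columns=cols).rename_axis("ex_nm") \
        .to_csv(outdir / "ex_loadings.csv", float_format="%.17g")
    pd.DataFrame(model.em_loadings, index=em_idx, columns=cols).rename_axis("em_nm") \
        .to_csv(outdir / "em_loadings.csv", float_format="%.17g")
    pd.DataFrame(model.scores, index=ids, columns=cols).rename_axis("sample_id") \
        .to_csv(outdir / "scores.csv", float_format="%.17g")
    diag = {
        "n_components": model.n_components,
        "explained_variance": model.explained_variance,
        "sse": model.sse,
        "n_iterations": model.n_iterations,
        "converged": model.converged,
        "seed": model.seed,
    }
    (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2, sort_keys=True))


def load_model(outdir) -> ParafacModel:
    outdir = Path(outdir)
    ex = pd.read_csv(outdir / "ex_loadings.csv", index_col=0)
    em = pd.read_csv(outdir / "em_loadings.csv", index_col=0)
    sc = pd.read_csv(outdir / "scores.csv", index_col=0)
    diag = json.loads((outdir / "diagnostics.json").read_text())
    return ParafacModel(
        n_components=diag["n_components"],
        ex_loadings=ex.to_numpy(),
        em_loadings=em.to_numpy(),
        scores=sc.to_numpy(),
        explained_variance=diag["explained_variance"],
        sse=diag["sse"],
        n_iterations=diag["n_iterations"],
        converged=diag["converged"],
        seed=diag["seed"],
        ex_nm=ex.index.to_numpy(dtype=float),
        em_nm=em.index.to_numpy(dtype=float),
        sample_ids=list(sc.index),
    )
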