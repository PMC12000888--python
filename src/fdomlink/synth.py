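"""Synthetic-data generators with machine-readable ground truth.

Every generator is a pure function of its parameters and seed, and returns
(or writes) a ``GroundTruth`` record sufficient to recompute the expected
analysis outputs: EEM stacks as low-rank mixtures of known Gaussian
fluorophores, absorbance spectra with known exponential slopes, Yule
phylogenies, neutral communities sampled from the Sloan stationary
distribution, niche-filtered communities with Brownian trait optima, and a
full two-group × two-matrix study-like bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import Phylogeny
from .community import FeatureTable
from .eem import EEM, AbsorbanceSpectrum, EEMDataset, raman_emission_nm, write_eem_csv
from .errors import FdomlinkError

__all__ = [
    "ComponentSpec",
    "GroundTruth",
    "default_components",
    "generate_eem_dataset",
    "generate_absorbance",
    "generate_phylogeny",
    "generate_neutral_communities",
    "generate_niche_communities",
    "generate_study_like_bundle",
]


@dataclass(frozen=True)
class ComponentSpec:
    """Gaussian fluorophore shape; ``ex_center2`` adds a secondary excitation peak."""

    label: str
    ex_center: float
    ex_width: float
    em_center: float
    em_width: float
    ex_center2: float | None = None
    ex_weight2: float = 0.6

    def __post_init__(self):
        if self.ex_width <= 0 or self.em_width <= 0:
            raise FdomlinkError("component widths must be positive")
        if self.em_center <= self.ex_center:
            raise FdomlinkError("emission peak must be red of the excitation peak")

    def ex_loading(self, ex_nm: np.ndarray) -> np.ndarray:
        v = np.exp(-0.5 * ((ex_nm - self.ex_center) / self.ex_width) ** 2)
        if self.ex_center2 is not None:
            v = v + self.ex_weight2 * np.exp(
                -0.5 * ((ex_nm - self.ex_center2) / self.ex_width) ** 2)
        return v / v.max()

    def em_loading(self, em_nm: np.ndarray) -> np.ndarray:
        v = np.exp(-0.5 * ((em_nm - self.em_center) / self.em_width) ** 2)
        return v / v.max()


def default_components() -> list[ComponentSpec]:
    """Four literature-typical fluorophores: two humic-like, two protein-like."""
    return [
        ComponentSpec("terrestrial humic-like", ex_center=250.0, ex_width=30.0,
                      em_center=460.0, em_width=45.0, ex_center2=340.0),
        ComponentSpec("microbial humic-like", ex_center=310.0, ex_width=25.0,
                      em_center=410.0, em_width=40.0),
        ComponentSpec("tyrosine-like", ex_center=275.0, ex_width=15.0,
                      em_center=304.0, em_width=18.0),
        ComponentSpec("tryptophan-like", ex_center=280.0, ex_width=16.0,
                      em_center=340.0, em_width=25.0),
    ]


class GroundTruth(dict):
    """A JSON-serializable record of generator parameters and latent truth."""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, sort_keys=True,
                                         default=_jsonify))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls(json.loads(Path(path).read_text()))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


DEFAULT_EX = np.arange(240.0, 451.0, 5.0)
DEFAULT_EM = np.arange(300.0, 621.0, 4.0)


def generate_eem_dataset(n_samples: int = 40,
                         components: list[ComponentSpec] | None = None,
                         weights: np.ndarray | None = None,
                         noise_sd: float | None = None,
                         snr: float | None = 50.0,
                         scatter: bool = False,
                         ex_nm: np.ndarray | None = None,
                         em_nm: np.ndarray | None = None,
                         seed: int = 0) -> tuple[EEMDataset, GroundTruth]:
    """Low-rank EEM stack: Σ_k w_ik · (em_k ⊗ ex_k) + optional scatter + noise.

    Noise is Gaussian; its level comes from ``noise_sd`` directly or from
    ``snr`` (signal RMS / noise SD). Truth stores loadings and mixing weights.
    """
    comps = components if components is not None else default_components()
    ex = np.asarray(ex_nm if ex_nm is not None else DEFAULT_EX, dtype=float)
    em = np.asarray(em_nm if em_nm is not None else DEFAULT_EM, dtype=float)
    k = len(comps)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    if weights is None:
        weights = rng.lognormal(mean=0.0, sigma=0.5, size=(n_samples, k))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_samples, k):
        raise FdomlinkError(f"weights shape {weights.shape} != ({n_samples}, {k})")
    if np.any(weights < 0):
        raise FdomlinkError("weights must be nonnegative")

    ex_load = np.column_stack([c.ex_loading(ex) for c in comps])
    em_load = np.column_stack([c.em_loading(em) for c in comps])
    for c in comps:
        if min(c.ex_width, c.em_width) < 0.75 * max(np.diff(ex).max(), np.diff(em).max()):
            import warnings
            warnings.warn(f"grid too coarse for component {c.label!r}", stacklevel=2)

    surfaces = np.einsum("jk,lk->kjl", em_load, ex_load)  # (K, em, ex)
    signal = np.einsum("ik,kjl->ijl", weights, surfaces)

    if noise_sd is None:
        noise_sd = 0.0 if snr is None else float(np.sqrt(np.mean(signal ** 2)) / snr)
    stack = signal + rng.normal(scale=noise_sd, size=signal.shape) if noise_sd > 0 \
        else signal.copy()

    if scatter:
        emg = em[:, None]
        exg = ex[None, :]
        ridge = (np.exp(-0.5 * ((emg - exg) / 6.0) ** 2)
                 + 0.4 * np.exp(-0.5 * ((emg - raman_emission_nm(ex)[None, :]) / 4.0) ** 2)
                 + 0.3 * np.exp(-0.5 * ((emg - 2.0 * exg) / 6.0) ** 2))
        amp = 3.0 * signal.max()
        stack = stack + amp * ridge[None, :, :]

    eems = [EEM(sample_id=f"SYN{i:03d}", ex_nm=ex, em_nm=em, intensity=stack[i])
            for i in range(n_samples)]
    truth = GroundTruth(
        generator="generate_eem_dataset",
        seed=seed,
        n_samples=n_samples,
        labels=[c.label for c in comps],
        ex_nm=ex, em_nm=em,
        ex_loadings=ex_load, em_loadings=em_load,
        weights=weights,
        noise_sd=noise_sd,
        scatter=scatter,
    )
    return EEMDataset(eems=eems), truth


def generate_absorbance(n: int = 1, slope_uv: float = 0.03,
                        slope_vis: float = 0.015, a_ref: float = 50.0,
                        noise_sd: float = 0.0, wl_break: float = 325.0,
                        wl_nm: np.ndarray | None = None,
                        seed: int = 0) -> tuple[list[AbsorbanceSpectrum], GroundTruth]:
    """Piecewise double-exponential absorbance spectra on a 230–800 nm comb.

    The Napierian absorption coefficient decays with slope ``slope_uv`` below
    ``wl_break`` and ``slope_vis`` above (continuous at the break), so the
    slope-ratio ground truth is exactly ``slope_uv / slope_vis``.
    """
    if slope_uv <= 0 or slope_vis <= 0:
        raise FdomlinkError("slopes must be positive")
    wl = np.asarray(wl_nm if wl_nm is not None else np.arange(230.0, 801.0), dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    path_m = 0.01  # 1 cm cuvette
    spectra = []
    for i in range(n):
        a_uv = a_ref * np.exp(-slope_uv * (wl - wl_break))
        a_vis = a_ref * np.exp(-slope_vis * (wl - wl_break))
        a = np.where(wl <= wl_break, a_uv, a_vis)
        if noise_sd > 0:
            a = a * np.exp(rng.normal(scale=noise_sd, size=a.shape))
        absorbance = a * path_m / 2.303
        spectra.append(AbsorbanceSpectrum(sample_id=f"ABS{i:03d}", wl_nm=wl,
                                          absorbance=absorbance, pathlength_cm=1.0))
    truth = GroundTruth(
        generator="generate_absorbance", seed=seed, n=n,
        slope_uv=slope_uv, slope_vis=slope_vis, slope_ratio=slope_uv / slope_vis,
        a_ref=a_ref, wl_break=wl_break, noise_sd=noise_sd,
    )
    return spectra, truth


def generate_phylogeny(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with unit birth rate; tips labelled ASV_0001…"""
    if n_tips < 2:
        raise FdomlinkError("need at least 2 tips")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))

    class _Node:
        __slots__ = ("children", "length", "label")

        def __init__(self):
            self.children = []
            self.length = 0.0
            self.label = None

    root = _Node()
    tips = [root]
    while len(tips) < n_tips:
        wait = rng.exponential(1.0 / len(tips))
        for t in tips:
            t.length += wait
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        left, right = _Node(), _Node()
        parent.children = [left, right]
        tips.extend([left, right])
    final_wait = rng.exponential(1.0 / len(tips))
    for t in tips:
        t.length += final_wait
    order = rng.permutation(n_tips)
    for rank, t in enumerate(tips):
        t.label = f"ASV_{order[rank] + 1:04d}"

    def newick(node: _Node) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.length:.10f}"

    return Phylogeny.from_newick(newick(root) + ";")


def logseries_metacommunity(n_taxa: int, theta: float = 0.999) -> np.ndarray:
    """Log-series relative abundances, descending, normalized to 1."""
    ranks = np.arange(1, n_taxa + 1)
    p = theta ** ranks / ranks
    return p / p.sum()


def generate_neutral_communities(tree: Phylogeny | None = None,
                                 n_taxa: int | None = None,
                                 metacommunity: np.ndarray | None = None,
                                 n_reads: int = 5000, m: float = 0.1,
                                 n_samples: int = 50,
                                 seed: int = 0) -> tuple[FeatureTable, GroundTruth]:
    """Communities from the Sloan stationary distribution.

    Per sample, local relative abundances are a Dirichlet draw with
    concentration ``N·m·p`` (whose marginals are the Sloan Beta
    distributions), followed by a multinomial of ``N`` reads.
    """
    if not (0 < m <= 1):
        raise FdomlinkError("m must lie in (0, 1]")
    if tree is not None:
        asv_ids = sorted(tree.tip_labels)
        n_taxa = len(asv_ids)
    else:
        if n_taxa is None:
            raise FdomlinkError("provide a tree or n_taxa")
        asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_taxa)]
    p = np.asarray(metacommunity, dtype=float) if metacommunity is not None \
        else logseries_metacommunity(n_taxa)
    if p.size != n_taxa or np.any(p <= 0):
        raise FdomlinkError("metacommunity must be positive with one entry per taxon")
    p = p / p.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    alpha = n_reads * m * p
    for s in range(n_samples):
        local = rng.dirichlet(alpha)
        counts[:, s] = rng.multinomial(n_reads, local)
    table = FeatureTable(counts, asv_ids, [f"S{s + 1:03d}" for s in range(n_samples)])
    truth = GroundTruth(
        generator="generate_neutral_communities", seed=seed,
        m=m, n_reads=n_reads, nm=n_reads * m, n_samples=n_samples,
        metacommunity=p, asv_ids=asv_ids,
    )
    return table, truth


def brownian_optima(tree: Phylogeny, sigma2: float = 1.0,
                    seed: int = 0) -> dict[str, float]:
    """Brownian-motion trait values at the tips (variance ∝ path length)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        parent_val = values.get(id(node.parent_node), 0.0)
        edge = node.edge.length or 0.0
        val = parent_val + rng.normal(scale=np.sqrt(sigma2 * edge)) if edge > 0 \
            else parent_val
        values[id(node)] = val
        if node.is_leaf():
            out[node.taxon.label] = float(val)
    return out


def generate_niche_communities(tree: Phylogeny, env: np.ndarray,
                               selection_strength: float = 5.0,
                               n_reads: int = 5000,
                               metacommunity: np.ndarray | None = None,
                               sigma2: float = 1.0,
                               optima_sd: float | None = None,
                               lottery_sd: float = 0.0,
                               seed: int = 0) -> tuple[FeatureTable, GroundTruth]:
    """Niche-filtered communities with phylogenetically conserved optima.

    Each taxon's environmental optimum evolves by Brownian motion along the
    tree (rescaled to standard deviation ``optima_sd`` when given, so the
    ``env`` values can be placed inside the trait range); sampling weights are
    ``exp(−s·(optimum − env)²)·p``, optionally multiplied by per-sample
    lognormal lottery noise (``lottery_sd``) to induce taxon turnover between
    replicate samples, followed by a multinomial draw. ``selection_strength``
    0 reduces to neutral-like multinomial sampling of the metacommunity.
    """
    if selection_strength < 0:
        raise FdomlinkError("selection strength must be >= 0")
    env = np.asarray(env, dtype=float)
    n_samples = env.size
    asv_ids = sorted(tree.tip_labels)
    n_taxa = len(asv_ids)
    p = np.asarray(metacommunity, dtype=float) if metacommunity is not None \
        else logseries_metacommunity(n_taxa)
    p = p / p.sum()
    optima_map = brownian_optima(tree, sigma2=sigma2, seed=seed)
    optima = np.array([optima_map[a] for a in asv_ids])
    if optima_sd is not None and optima.std() > 0:
        optima = optima / optima.std() * optima_sd
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        w = np.exp(-selection_strength * (optima - env[s]) ** 2) * p
        if lottery_sd > 0:
            w = w * rng.lognormal(0.0, lottery_sd, n_taxa)
        if w.sum() <= 0:
            w = p.copy()
        counts[:, s] = rng.multinomial(n_reads, w / w.sum())
    table = FeatureTable(counts, asv_ids, [f"S{s + 1:03d}" for s in range(n_samples)])
    truth = GroundTruth(
        generator="generate_niche_communities", seed=seed,
        selection_strength=selection_strength, n_reads=n_reads,
        env=env, optima=optima, sigma2=sigma2,
        optima_sd=optima_sd, lottery_sd=lottery_sd,
        metacommunity=p, asv_ids=asv_ids,
    )
    return table, truth


def niche_filtering_fixture(seed: int = 0, n_tips: int = 2000,
                            n_per_group: int = 10, n_reads: int = 2500):
    """Two-habitat strong-filtering fixture tuned for βNTI calibration.

    Ten samples per habitat with environments at ±2 (jitter 0.3) on a
    2000-tip tree, uniform metacommunity, selection strength 12 and lottery
    noise 1.2; within-habitat pairs are dominated by homogeneous selection.
    """
    tree = generate_phylogeny(n_tips, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    env = np.concatenate([rng.normal(2.0, 0.3, n_per_group),
                          rng.normal(-2.0, 0.3, n_per_group)])
    table, truth = generate_niche_communities(
        tree, env, selection_strength=12.0, n_reads=n_reads,
        metacommunity=np.ones(n_tips) / n_tips, optima_sd=2.0,
        lottery_sd=1.2, seed=seed)
    truth["groups"] = ["A"] * n_per_group + ["B"] * n_per_group
    return tree, table, truth


# ---- study-like bundle ---------------------------------------------------

_BUNDLE_GROUPS = [("HH", 6), ("LH", 6), ("R", 4)]

# target mixing-weight profiles (C1 terr-humic, C2 micro-humic, C3 tyr, C4 trp)
_WEIGHT_PROFILES = {
    ("HH", "sediment"): np.array([1.0, 1.2, 4.0, 3.0]),   # protein-dominated
    ("LH", "sediment"): np.array([3.5, 3.0, 0.8, 0.7]),   # humic-dominated
    ("R", "sediment"): np.array([3.5, 2.5, 0.4, 0.6]),
    ("HH", "water"): np.array([2.0, 2.0, 1.5, 1.5]),
    ("LH", "water"): np.array([2.5, 2.2, 0.8, 0.8]),
    ("R", "water"): np.array([3.0, 2.2, 0.5, 0.6]),
}


def generate_study_like_bundle(seed: int = 7, out_dir=None,
                               n_taxa: int = 120,
                               n_reads: int = 4000) -> dict:
    """A full desk-scale study: 16 sites × {water, sediment}.

    EEMs have group-dependent component weights (HH sediment protein-
    dominated, LH sediment humic-dominated), matching absorbance and DOC,
    one shared phylogeny, neutral communities for the water samples and
    niche-filtered communities (environment differing by group) for the
    sediments. If ``out_dir`` is given the fixtures are also written in the
    pipeline's external text formats alongside a ``groundtruth.json``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    # tyrosine-like shifted off the water-Raman line (em ~303 at ex 275) so
    # the protein peak survives scatter excision during preprocessing
    comps = default_components()
    comps[2] = dataclasses.replace(comps[2], em_center=314.0, em_width=16.0)
    comps[3] = dataclasses.replace(comps[3], em_center=348.0)
    sample_rows = []
    sample_ids = []
    weights = []
    for group, count in _BUNDLE_GROUPS:
        for i in range(count):
            site = f"{group}{i + 1}"
            for matrix in ("water", "sediment"):
                sid = f"{site}_{matrix[0].upper()}"
                base = _WEIGHT_PROFILES[(group, matrix)]
                w = base * rng.lognormal(0.0, 0.15, size=4)
                doc = float(rng.uniform(10, 15) if matrix == "water"
                            else rng.uniform(40, 150))
                sample_ids.append(sid)
                weights.append(w)
                sample_rows.append({
                    "sample_id": sid, "site": site, "group": group,
                    "matrix_type": matrix, "doc_mg_per_L": round(doc, 2),
                    "WT": round(float(rng.uniform(14, 22)), 2),
                    "pH": round(float(rng.uniform(7.2, 8.8)), 2),
                    "DO": round(float(rng.uniform(5, 10)), 2),
                    "TN": round(float(rng.uniform(0.5, 3.5)), 3),
                    "TP": round(float(rng.uniform(0.02, 0.4)), 3),
                })
    weights = np.asarray(weights)
    meta = pd.DataFrame(sample_rows).set_index("sample_id")

    ds, eem_truth = generate_eem_dataset(
        n_samples=len(sample_ids), components=comps, weights=weights,
        snr=50.0, scatter=False, seed=seed)
    eems = [EEM(sample_id=sid, ex_nm=e.ex_nm, em_nm=e.em_nm, intensity=e.intensity)
            for sid, e in zip(sample_ids, ds.eems)]
    ds = EEMDataset(eems=eems, meta=meta)

    spectra, abs_truth = generate_absorbance(
        n=len(sample_ids), slope_uv=0.028, slope_vis=0.016, a_ref=10.0,
        noise_sd=0.01, seed=seed)
    spectra = [AbsorbanceSpectrum(sample_id=sid, wl_nm=sp.wl_nm,
                                  absorbance=sp.absorbance)
               for sid, sp in zip(sample_ids, spectra)]

    # instrument blank: water Raman + Rayleigh ridges only
    ex_g = ds.ex_nm[None, :]
    em_g = ds.em_nm[:, None]
    blank_intensity = (
        20.0 * np.exp(-0.5 * ((em_g - raman_emission_nm(ds.ex_nm)[None, :]) / 4.0) ** 2)
        + 40.0 * np.exp(-0.5 * ((em_g - ex_g) / 5.0) ** 2)
    )
    blank = EEM(sample_id="BLANK", ex_nm=ds.ex_nm, em_nm=ds.em_nm,
                intensity=blank_intensity)

    tree = generate_phylogeny(n_taxa, seed=seed)
    water_ids = [s for s in sample_ids if s.endswith("_W")]
    sed_ids = [s for s in sample_ids if s.endswith("_S")]
    water_table, water_truth = generate_neutral_communities(
        tree=tree, n_reads=n_reads, m=0.1, n_samples=len(water_ids), seed=seed)
    water_table = FeatureTable(water_table.counts, water_table.asv_ids, water_ids)
    env_by_group = {"HH": 2.0, "LH": -2.0, "R": 0.0}
    sed_env = np.array([env_by_group[meta.at[s, "group"]] for s in sed_ids])
    sed_table, sed_truth = generate_niche_communities(
        tree=tree, env=sed_env, selection_strength=5.0, n_reads=n_reads,
        seed=seed)
    sed_table = FeatureTable(sed_table.counts, sed_table.asv_ids, sed_ids)

    # simple two-rank taxonomy: contiguous ASV blocks as phyla
    n_phyla = 6
    asv_sorted = sorted(tree.tip_labels)
    tax = pd.DataFrame({
        "phylum": [f"Phylum_{(i * n_phyla) // len(asv_sorted) + 1}"
                   for i in range(len(asv_sorted))],
        "genus": [f"Genus_{i % 25 + 1}" for i in range(len(asv_sorted))],
    }, index=asv_sorted)
    water_table.taxonomy = tax
    sed_table.taxonomy = tax

    truth = GroundTruth(
        generator="generate_study_like_bundle", seed=seed,
        sample_ids=sample_ids,
        weights=weights,
        component_labels=[c.label for c in comps],
        protein_components=[2, 3],
        humic_components=[0, 1],
        protein_dominant_group=("HH", "sediment"),
        humic_dominant_group=("LH", "sediment"),
        eem_truth=dict(eem_truth),
        absorbance_truth=dict(abs_truth),
        water_truth=dict(water_truth),
        sediment_truth=dict(sed_truth),
        sediment_env=sed_env,
    )
    bundle = {
        "dataset": ds,
        "meta": meta,
        "blank": blank,
        "absorbance": spectra,
        "tree": tree,
        "water_table": water_table,
        "sediment_table": sed_table,
        "taxonomy": tax,
        "truth": truth,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    eem_dir = out_dir / "eems"
    eem_dir.mkdir(exist_ok=True)
    for e in bundle["dataset"].eems:
        write_eem_csv(e, eem_dir / f"{e.sample_id}.csv")
    write_eem_csv(bundle["blank"], out_dir / "blank.csv")
    abs_dir = out_dir / "absorbance"
    abs_dir.mkdir(exist_ok=True)
    for sp in bundle["absorbance"]:
        pd.DataFrame({"wl_nm": sp.wl_nm, "A": sp.absorbance}).to_csv(
            abs_dir / f"{sp.sample_id}.csv", index=False, float_format="%.17g")
    bundle["meta"].reset_index().to_csv(out_dir / "metadata.tsv", sep="\t",
                                        index=False)
    (out_dir / "tree.nwk").write_text(bundle["tree"].to_newick() + "\n")
    bundle["water_table"].to_tsv(out_dir / "water_counts.tsv")
    bundle["sediment_table"].to_tsv(out_dir / "sediment_counts.tsv")
    tax = bundle["taxonomy"].copy()
    tax.index.name = "asv_id"
    tax.to_csv(out_dir / "taxonomy.tsv", sep="\t")
    bundle["truth"].save(out_dir / "groundtruth.json")
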