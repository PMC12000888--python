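"""Pipeline orchestration: config validation, stage execution, report assembly.

``run_pipeline`` executes the stages in dependency order on a study bundle
directory (as written by :func:`fdomlink.synth.generate_study_like_bundle`):

    preprocess → parafac → indices → diversity → assembly → ncm → network → linkage

Every output file is written deterministically (fixed float formatting, sorted
keys) so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import Phylogeny, assembly_fractions, beta_nti
from .community import FeatureTable, alpha_diversity, bray_curtis, group_compare, nmds
from .eem import EEMDataset, load_eem_csv, load_absorbance_csv, load_metadata_tsv, \
    preprocess as preprocess_eem, write_eem_csv, ScatterWidths
from .errors import ConfigError, DataError, FdomlinkError
from .linkage import aggregate_taxa, bnti_fdom_correlation, spearman_map
from .networks import build_network, network_metrics, prevalence_filter
from .neutral import ncm_fit
from .optical import compute_indices
from .parafac import (
    component_fingerprints,
    fit_parafac,
    fmax_scores,
    model_order_scan,
    percent_composition,
    save_model,
    split_half_validate,
)

ALL_STAGES = ("preprocess", "parafac", "indices", "diversity", "assembly",
              "ncm", "network", "linkage")

_FLOAT = "%.12g"


@dataclass
class PipelineConfig:
    input_dir: str = "."
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # preprocessing
    em_max: float = 600.0
    ex_min: float = 250.0
    raman_ex_ref: float = 350.0
    raman_band: tuple[float, float] = (371.0, 428.0)
    scatter_widths: tuple[float, float, float] = (10.0, 5.0, 10.0)
    # parafac
    parafac_k: int = 4
    parafac_k_scan: tuple[int, int] | None = None
    parafac_n_starts: int = 3
    parafac_max_iter: int = 1500
    parafac_tol: float = 1e-8
    split_half_threshold: float = 0.95
    # indices / diversity
    hix_variant: str = "zsolnay"
    shannon_base: float = 2.0
    nmds_k: int = 2
    # assembly / ncm
    bnti_n_null: int = 999
    bnti_weighted: bool = True
    ncm_detection_limit: float | None = None
    # network
    network_rho_min: float = 0.6
    network_q_max: float = 0.05
    network_min_prevalence: float = 0.5
    network_rank: str = "genus"
    # linkage
    linkage_rank: str = "phylum"
    linkage_n_perm: int = 999

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        data = dict(data)
        for key in ("stages", "raman_band", "scatter_widths", "parafac_k_scan"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        out["raman_band"] = list(self.raman_band)
        out["scatter_widths"] = list(self.scatter_widths)
        if self.parafac_k_scan is not None:
            out["parafac_k_scan"] = list(self.parafac_k_scan)
        return out

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---- bundle I/O ----------------------------------------------------------


def load_bundle(input_dir) -> dict:
    """Load a study bundle directory written in the pipeline's text formats."""
    root = Path(input_dir)
    if not root.is_dir():
        raise DataError(f"input directory {root} does not exist")
    eem_dir = root / "eems"
    if not eem_dir.is_dir():
        raise DataError(f"missing EEM directory {eem_dir}")
    meta = load_metadata_tsv(root / "metadata.tsv")
    eems = [load_eem_csv(p) for p in sorted(eem_dir.glob("*.csv"))]
    ds = EEMDataset(eems=eems, meta=meta)
    blank_path = root / "blank.csv"
    blank = load_eem_csv(blank_path) if blank_path.exists() else None
    absorbance = {}
    abs_dir = root / "absorbance"
    if abs_dir.is_dir():
        for p in sorted(abs_dir.glob("*.csv")):
            sp = load_absorbance_csv(p)
            absorbance[sp.sample_id] = sp
    tree_path = root / "tree.nwk"
    tree = Phylogeny.from_file(tree_path) if tree_path.exists() else None
    tax_path = root / "taxonomy.tsv"
    tables = {}
    for matrix, fname in (("water", "water_counts.tsv"), ("sediment", "sediment_counts.tsv")):
        p = root / fname
        if p.exists():
            tables[matrix] = FeatureTable.from_tsv(
                p, taxonomy_path=tax_path if tax_path.exists() else None)
    return {"dataset": ds, "meta": meta, "blank": blank,
            "absorbance": absorbance, "tree": tree, "tables": tables}


# ---- stages --------------------------------------------------------------


def stage_preprocess(bundle: dict, cfg: PipelineConfig) -> EEMDataset:
    if bundle["blank"] is None:
        raise DataError("preprocess stage requires a blank EEM (blank.csv)")
    widths = ScatterWidths(*cfg.scatter_widths)
    out = []
    for e in bundle["dataset"].eems:
        sp = bundle["absorbance"].get(e.sample_id)
        if sp is None:
            raise DataError(f"no absorbance spectrum for sample {e.sample_id!r}")
        corrected, _ = preprocess_eem(
            e, bundle["blank"], sp, em_max=cfg.em_max, ex_min=cfg.ex_min,
            widths=widths, ex_ref=cfg.raman_ex_ref, em_band=cfg.raman_band)
        out.append(corrected)
    return EEMDataset(eems=out, meta=bundle["meta"])


def stage_parafac(pre: EEMDataset, cfg: PipelineConfig):
    model = fit_parafac(pre, cfg.parafac_k, n_starts=cfg.parafac_n_starts,
                        max_iter=cfg.parafac_max_iter, tol=cfg.parafac_tol,
                        seed=cfg.seed)
    scan = None
    if cfg.parafac_k_scan is not None:
        lo, hi = cfg.parafac_k_scan
        scan = model_order_scan(pre, range(lo, hi + 1),
                                n_starts=cfg.parafac_n_starts,
                                max_iter=cfg.parafac_max_iter,
                                tol=cfg.parafac_tol, seed=cfg.seed)
    return model, scan


def stage_indices(pre: EEMDataset, bundle: dict, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for e in pre.eems:
        sp = bundle["absorbance"].get(e.sample_id)
        doc = None
        if bundle["meta"] is not None and "doc_mg_per_L" in bundle["meta"].columns:
            doc = float(bundle["meta"].at[e.sample_id, "doc_mg_per_L"])
        idx = compute_indices(e, sp, doc, hix_variant=cfg.hix_variant)
        rows.append(dataclasses.asdict(idx))
    df = pd.DataFrame(rows).set_index("sample_id")
    return df.join(bundle["meta"], how="left")


def stage_diversity(tables: dict, cfg: PipelineConfig) -> dict:
    out = {}
    for matrix, table in tables.items():
        alpha = alpha_diversity(table, base=cfg.shannon_base)
        dist = bray_curtis(table)
        res = nmds(dist, k=cfg.nmds_k, seed=cfg.seed)
        coords = pd.DataFrame(
            res.coordinates, index=table.sample_ids,
            columns=[f"NMDS{i + 1}" for i in range(cfg.nmds_k)])
        out[matrix] = {"alpha": alpha, "bray_curtis": dist,
                       "nmds_coords": coords, "nmds_stress": res.stress}
    return out


def stage_assembly(tables: dict, tree: Phylogeny, cfg: PipelineConfig) -> dict:
    if tree is None:
        raise DataError("assembly stage requires a phylogeny (tree.nwk)")
    out = {}
    for matrix, table in tables.items():
        res = beta_nti(table, tree, n_null=cfg.bnti_n_null,
                       weighted=cfg.bnti_weighted, seed=cfg.seed)
        pct_stoch, pct_det = assembly_fractions(res.values())
        out[matrix] = {"bnti": res, "pct_stochastic": pct_stoch,
                       "pct_deterministic": pct_det}
    return out


def stage_ncm(tables: dict, cfg: PipelineConfig) -> dict:
    out = {}
    for matrix, table in tables.items():
        out[matrix] = ncm_fit(table, d=cfg.ncm_detection_limit)
    return out


def _dom_feature_frame(model, pre: EEMDataset) -> pd.DataFrame:
    fmax = fmax_scores(model)
    labels = [fp.label for fp in component_fingerprints(model)]
    names = [f"C{k + 1} ({labels[k]})" for k in range(model.n_components)]
    return pd.DataFrame(fmax.T, index=names, columns=pre.sample_ids)


def stage_network(tables: dict, dom: pd.DataFrame, meta: pd.DataFrame,
                  cfg: PipelineConfig) -> dict:
    env_cols = [c for c in meta.columns
                if c not in {"site", "group", "matrix_type"}
                and np.issubdtype(meta[c].dtype, np.number)]
    out = {}
    for matrix, table in tables.items():
        if table.taxonomy is not None:
            taxa = aggregate_taxa(table, cfg.network_rank)
        else:
            filtered = prevalence_filter(
                table, min_prevalence=cfg.network_min_prevalence)
            taxa = pd.DataFrame(filtered.relative_abundance(),
                                index=filtered.asv_ids,
                                columns=filtered.sample_ids)
        # prevalence filter on the aggregated variables
        prevalent = (taxa > 0).mean(axis=1) >= cfg.network_min_prevalence
        taxa = taxa.loc[prevalent]
        samples = list(taxa.columns)
        frames = [taxa]
        kinds = {str(t): "taxon" for t in taxa.index}
        if dom is not None:
            dom_m = dom[samples]
            frames.append(dom_m)
            kinds.update({str(i): "dom_component" for i in dom_m.index})
        env = meta.loc[samples, env_cols].T
        frames.append(env)
        kinds.update({str(i): "environment" for i in env.index})
        features = pd.concat(frames)
        net = build_network(features, kinds=kinds, rho_min=cfg.network_rho_min,
                            q_max=cfg.network_q_max)
        out[matrix] = {"network": net, "metrics": network_metrics(net)}
    return out


def stage_linkage(tables: dict, dom: pd.DataFrame, assembly: dict,
                  cfg: PipelineConfig) -> dict:
    out = {}
    for matrix, table in tables.items():
        entry = {}
        if table.taxonomy is not None:
            taxa = aggregate_taxa(table, cfg.linkage_rank)
            entry["spearman_map"] = spearman_map(taxa, dom)
        if matrix in (assembly or {}):
            entry["mantel"] = bnti_fdom_correlation(
                assembly[matrix]["bnti"], dom, n_perm=cfg.linkage_n_perm,
                seed=cfg.seed)
        out[matrix] = entry
    return out


# ---- report assembly -----------------------------------------------------


def _write_matrix_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=_FLOAT)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run all configured stages and write the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(config.input_dir)
    stages = config.stages
    ctx: dict = {}

    def active(name: str) -> bool:
        return name in stages

    if active("preprocess"):
        pre = stage_preprocess(bundle, config)
        ctx["pre"] = pre
        d = out / "preprocess"
        d.mkdir(exist_ok=True)
        for e in pre.eems:
            write_eem_csv(e, d / f"{e.sample_id}.csv")

    if active("parafac"):
        if "pre" not in ctx:
            raise ConfigError("parafac stage requires the preprocess stage")
        model, scan = stage_parafac(ctx["pre"], config)
        ctx["model"] = model
        d = out / "parafac"
        save_model(model, d)
        fps = component_fingerprints(model)
        pd.DataFrame([dataclasses.asdict(fp) for fp in fps]).to_csv(
            d / "fingerprints.csv", index=False, float_format=_FLOAT)
        fmax = fmax_scores(model)
        fmax_df = pd.DataFrame(fmax, index=ctx["pre"].sample_ids,
                               columns=[f"C{k + 1}" for k in range(model.n_components)])
        fmax_df.rename_axis("sample_id").to_csv(d / "fmax.csv", float_format=_FLOAT)
        pct = percent_composition(fmax)
        pd.DataFrame(pct, index=ctx["pre"].sample_ids,
                     columns=fmax_df.columns).rename_axis("sample_id").to_csv(
            d / "percent_composition.csv", float_format=_FLOAT)
        if scan is not None:
            scan.to_csv(d / "model_order_scan.csv", index=False, float_format=_FLOAT)
        try:
            report = split_half_validate(
                ctx["pre"], config.parafac_k, threshold=config.split_half_threshold,
                seed=config.seed, n_starts=config.parafac_n_starts,
                max_iter=config.parafac_max_iter, tol=config.parafac_tol)
            report.records.to_csv(d / "split_half.csv", index=False,
                                  float_format=_FLOAT)
            (d / "split_half.json").write_text(json.dumps(
                {"passed": report.passed, "threshold": report.threshold,
                 "min_congruence": report.min_congruence}, indent=2, sort_keys=True))
        except FdomlinkError as exc:
            (d / "split_half.json").write_text(json.dumps(
                {"passed": None, "error": str(exc)}, indent=2, sort_keys=True))
        ctx["dom"] = _dom_feature_frame(model, ctx["pre"])

    if active("indices"):
        if "pre" not in ctx:
            raise ConfigError("indices stage requires the preprocess stage")
        idx = stage_indices(ctx["pre"], bundle, config)
        d = out / "indices"
        d.mkdir(exist_ok=True)
        _write_matrix_csv(idx, d / "optical_indices.csv")
        ctx["indices"] = idx

    tables = bundle["tables"]
    if active("diversity") and tables:
        div = stage_diversity(tables, config)
        d = out / "diversity"
        d.mkdir(exist_ok=True)
        for matrix, res in div.items():
            _write_matrix_csv(res["alpha"], d / f"alpha_{matrix}.csv")
            _write_matrix_csv(res["nmds_coords"], d / f"nmds_{matrix}.csv")
            (d / f"nmds_{matrix}.json").write_text(json.dumps(
                {"stress": res["nmds_stress"]}, indent=2, sort_keys=True))

    if active("assembly") and tables:
        asm = stage_assembly(tables, bundle["tree"], config)
        ctx["assembly"] = asm
        d = out / "assembly"
        d.mkdir(exist_ok=True)
        summary = {}
        for matrix, res in asm.items():
            res["bnti"].to_long().to_csv(d / f"bnti_{matrix}.csv", index=False,
                                         float_format=_FLOAT)
            summary[matrix] = {"pct_stochastic": res["pct_stochastic"],
                               "pct_deterministic": res["pct_deterministic"]}
        (d / "assembly_fractions.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))

    if active("ncm") and tables:
        fits = stage_ncm(tables, config)
        d = out / "ncm"
        d.mkdir(exist_ok=True)
        for matrix, fit in fits.items():
            fit.per_asv.to_csv(d / f"ncm_{matrix}_per_asv.csv", index=False,
                               float_format=_FLOAT)
            fit.to_json(d / f"ncm_{matrix}.json")

    if active("network") and tables:
        nets = stage_network(tables, ctx.get("dom"), bundle["meta"], config)
        d = out / "network"
        d.mkdir(exist_ok=True)
        for matrix, res in nets.items():
            res["network"].edge_csv(d / f"edges_{matrix}.csv")
            res["network"].to_graphml(d / f"network_{matrix}.graphml")
            (d / f"metrics_{matrix}.json").write_text(json.dumps(
                res["metrics"].as_dict(), indent=2, sort_keys=True))

    if active("linkage") and tables:
        if "dom" not in ctx:
            raise ConfigError("linkage stage requires the parafac stage")
        link = stage_linkage(tables, ctx["dom"], ctx.get("assembly"), config)
        d = out / "linkage"
        d.mkdir(exist_ok=True)
        for matrix, entry in link.items():
            if "spearman_map" in entry:
                entry["spearman_map"].to_long().to_csv(
                    d / f"spearman_{matrix}.csv", index=False, float_format=_FLOAT)
            if "mantel" in entry:
                pd.DataFrame([dataclasses.asdict(r) for r in entry["mantel"]]) \
                    .to_csv(d / f"mantel_{matrix}.csv", index=False,
                            float_format=_FLOAT)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True))
    return out
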