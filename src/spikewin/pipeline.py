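"""End-to-end orchestration: simulate/load -> count -> normalize -> test ->
compartments -> states, with a reproducibility manifest.

A single YAML config drives every stage; identical (config, seed) pairs
produce byte-identical outputs and manifest checksums.  Stages write plain
TSV/BED/bedGraph files into the output directory and the manifest records
per-stage row counts and sha256 checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomic_io import GenomicInterval, read_blacklist, read_chrom_sizes, read_fragments
from .window_counting import (
    apply_blacklist,
    count_fragments,
    estimate_background,
    filter_by_background,
    fragments_to_frames,
    tile_windows,
)
from .normalization import (
    build_spike_controls,
    compute_offsets,
    compute_pc1_covariate,
    estimate_ruv_factors,
    spike_qc,
)
from .differential import (
    build_design,
    classify_trend,
    cluster_windows,
    combine_simes,
    estimate_dispersions,
    test_windows,
)
from .compartments import bin_counts, compartment_dissimilarity, compartment_profile
from .chromatin_states import (
    call_consensus,
    collapse_states,
    load_super_state_map,
    simulate_segmentations,
    state_composition,
)
from . import synthetic_data as synth

log = logging.getLogger("spikewin")

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "spikewin_out",
    "counting": {
        "width": 150,
        "step": 50,
        "max_fragment": 500,
        "background_bin": 1000,
        "min_fold": 3.0,
        "filter_mode": "pooled",
        "spike_tile": 5000,
    },
    "normalization": {"ruv_k": 1, "mode": "ruv", "use_pc1": False},
    "differential": {
        "max_gap": 100,
        "max_width": 5000,
        "fold": 1.5,
        "q": 0.05,
        "contrast": "anova",
    },
    "compartments": {"enabled": True, "bin_width": 100000, "reference": "solvent"},
    "states": {"enabled": False, "map": None, "min_fraction": 0.5, "simulate": False},
    "blacklist": None,
}


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def demo_config() -> dict:
    """The bundled simulation-backed demo configuration."""
    ref = resources.files("spikewin.data").joinpath("demo_config.yaml")
    return yaml.safe_load(ref.read_text())


def validate_config(config: dict) -> dict:
    """Normalize a config against defaults; aggregate all violations."""
    cfg = _merge(DEFAULTS, config or {})
    errors: list[str] = []
    has_sim = "simulation" in cfg and cfg["simulation"]
    has_inputs = "inputs" in cfg and cfg["inputs"]
    if not has_sim and not has_inputs:
        errors.append("config needs either a 'simulation' or an 'inputs' section")
    if has_sim and has_inputs:
        errors.append("'simulation' and 'inputs' are mutually exclusive")
    c = cfg["counting"]
    if c["width"] <= 0 or c["step"] <= 0:
        errors.append("counting.width and counting.step must be positive")
    if c["max_fragment"] <= 0:
        errors.append("counting.max_fragment must be positive")
    if c["min_fold"] <= 0:
        errors.append("counting.min_fold must be positive")
    n_samples = None
    if has_sim:
        n_samples = 3 * int(cfg["simulation"].get("n_replicates", 3))
    elif has_inputs:
        frags = cfg["inputs"].get("fragments", {})
        n_samples = len(frags)
        for sid, p in frags.items():
            if not Path(p).exists():
                errors.append(f"inputs.fragments[{sid!r}]: missing file {p}")
        cs = cfg["inputs"].get("chrom_sizes")
        if not cs:
            errors.append("inputs.chrom_sizes is required")
        elif not Path(cs).exists():
            errors.append(f"inputs.chrom_sizes: missing file {cs}")
        conds = cfg["inputs"].get("conditions", {})
        missing = set(frags) - set(conds)
        if missing:
            errors.append(f"inputs.conditions missing for samples {sorted(missing)}")
    if n_samples is not None and cfg["normalization"]["ruv_k"] >= max(n_samples, 1):
        errors.append(
            f"normalization.ruv_k={cfg['normalization']['ruv_k']} must be < "
            f"n_samples={n_samples}"
        )
    if cfg["blacklist"] is not None and not Path(cfg["blacklist"]).exists():
        errors.append(f"blacklist: missing file {cfg['blacklist']}")
    st = cfg["states"]
    if st["enabled"] and not st["simulate"]:
        segs = st.get("segmentations") or {}
        if not segs:
            errors.append("states.enabled requires states.segmentations or states.simulate")
        for sid, p in segs.items():
            if not Path(p).exists():
                errors.append(f"states.segmentations[{sid!r}]: missing file {p}")
    if errors:
        raise ConfigError(errors)
    return cfg


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], **counts: int) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": {k: str(p) for k, p in outputs.items()},
                "checksums": {k: _sha256(p) for k, p in outputs.items()},
            }
        )
        self.counts.update(counts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "stages": self.stages,
                "counts": self.counts,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> RunManifest:
    """Execute all configured stages and write outputs plus a manifest."""
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir if out_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, version=__version__, seed=seed)

    # --- stage: inputs / simulation ---------------------------------------
    if cfg.get("simulation"):
        sim = cfg["simulation"]
        sim_cfg = synth.default_config(
            n_replicates=int(sim.get("n_replicates", 3)),
            depth=float(sim.get("depth", 40_000)),
            technical_sd=float(sim.get("technical_sd", 0.0)),
            duplication_rate=float(sim.get("duplication_rate", 0.10)),
            seed=seed,
        )
        fragments, truth = synth.simulate_experiment(sim_cfg)
        chrom_sizes = sim_cfg.chrom_sizes()
        conditions = {s.sample_id: s.condition for s in sim_cfg.samples}
        truth_path = out / "truth_regions.tsv"
        truth.regions.to_csv(truth_path, sep="\t", index=False)
        tsamp_path = out / "truth_samples.tsv"
        truth.samples.to_csv(tsamp_path, sep="\t", index=False)
        manifest.record(
            "simulate",
            {"truth_regions": truth_path, "truth_samples": tsamp_path},
            n_samples=len(conditions),
            n_planted_regions=len(truth.regions),
        )
    else:
        inputs = cfg["inputs"]
        chrom_sizes = read_chrom_sizes(
            inputs["chrom_sizes"], inputs.get("spike_contigs", ["lambda", "phiX"])
        )
        fragments = {
            sid: pd.DataFrame(
                [
                    (r.interval.chrom, r.interval.start, r.interval.end)
                    for r in read_fragments(path, chrom_sizes, sample_id=sid)
                ],
                columns=["chrom", "start", "end"],
            )
            for sid, path in inputs["fragments"].items()
        }
        conditions = dict(inputs["conditions"])
        manifest.record("load", {}, n_samples=len(conditions))

    blacklist = (
        read_blacklist(cfg["blacklist"]) if cfg["blacklist"] else []
    )
    samples = sorted(conditions)

    # --- stage: counting ---------------------------------------------------
    c = cfg["counting"]
    grid = tile_windows(chrom_sizes, width=c["width"], step=c["step"], spike_tile=c["spike_tile"])
    counts = count_fragments(fragments, grid, max_fragment=c["max_fragment"], sample_order=samples)
    counts, n_blacklisted = apply_blacklist(counts, blacklist)
    background = estimate_background(
        fragments, chrom_sizes, c["background_bin"], blacklist=blacklist, sample_order=samples
    )
    retention = filter_by_background(counts, background, min_fold=c["min_fold"], mode=c["filter_mode"])
    counts.retained = retention.retained
    retained_path = out / "retained_windows.tsv"
    ret = counts.subset_rows(retention.retained)
    ret.to_frame().to_csv(retained_path, sep="\t", index=False)
    manifest.record(
        "count",
        {"retained_windows": retained_path},
        n_windows_tiled=retention.n_input,
        n_windows_blacklisted=n_blacklisted,
        n_windows_retained=retention.n_retained,
    )

    # --- stage: normalization ---------------------------------------------
    nz = cfg["normalization"]
    controls = build_spike_controls(counts)
    factors = estimate_ruv_factors(counts, controls, k=int(nz["ruv_k"]))
    offsets = compute_offsets(counts, factors, mode=nz["mode"])
    qc = spike_qc(counts)
    covs = []
    cov_names = []
    if offsets.use_ruv_covariates:
        covs.append(factors.W)
        cov_names += [f"ruv{i + 1}" for i in range(factors.k)]
    if nz["use_pc1"]:
        host_retained = counts.subset_rows(retention.retained | counts.is_spike)
        covs.append(compute_pc1_covariate(host_retained)[:, None])
        cov_names.append("pc1")
    covariates = np.hstack(covs) if covs else None
    norm_path = out / "normalization.tsv"
    pd.DataFrame(
        {
            "sample_id": counts.samples,
            "condition": [conditions[s] for s in counts.samples],
            "log_library": offsets.log_library,
            "lambda_fraction": qc.lambda_fraction,
            "phiX_fraction": qc.phiX_fraction if qc.phiX_fraction is not None else np.nan,
            **{f"ruv{i + 1}": factors.W[:, i] for i in range(factors.k)},
        }
    ).to_csv(norm_path, sep="\t", index=False)
    manifest.record("normalize", {"normalization": norm_path}, ruv_k=factors.k)

    # --- stage: differential ----------------------------------------------
    d = cfg["differential"]
    host_ret = counts.subset_rows(retention.retained)
    cond_list = [conditions[s] for s in counts.samples]
    design = build_design(
        list(counts.samples), cond_list, covariates=covariates,
        covariate_names=cov_names or None,
    )
    y = host_ret.counts
    off = offsets.log_library
    disp = estimate_dispersions(y, design, off)
    wtest = test_windows(y, design, off, disp, contrast=d["contrast"])
    cids = cluster_windows(
        host_ret.chroms, host_ret.starts, host_ret.ends,
        max_gap=d["max_gap"], max_width=d["max_width"],
    )
    clusters = combine_simes(wtest, cids, host_ret.chroms, host_ret.starts, host_ret.ends)
    clusters = classify_trend(clusters, fold=d["fold"], q_threshold=d["q"])
    clusters_path = out / "clusters.tsv"
    clusters.to_csv(clusters_path, sep="\t", index=False)
    sig = clusters[clusters["qvalue"] < d["q"]]
    sig_bed = out / "significant_clusters.bed"
    with open(sig_bed, "w") as fh:
        for _, row in sig.iterrows():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.trend}\t{row.qvalue:.3g}\n")
    trend_counts = clusters["trend"].value_counts().to_dict()
    manifest.record(
        "differential",
        {"clusters": clusters_path, "significant_clusters": sig_bed},
        n_clusters=len(clusters),
        n_significant=int(len(sig)),
        n_trend_up=int(trend_counts.get("up", 0)),
        n_trend_down=int(trend_counts.get("down", 0)),
        n_trend_none=int(trend_counts.get("none", 0)),
    )

    # --- stage: compartments ----------------------------------------------
    if cfg["compartments"]["enabled"]:
        cp = cfg["compartments"]
        bins = bin_counts(fragments, chrom_sizes, bin_width=cp["bin_width"], blacklist=blacklist,
                          sample_order=samples)
        ref_cond = cp["reference"]
        groups: dict[str, list[str]] = {}
        for sid, cond in conditions.items():
            groups.setdefault(cond, []).append(sid)
        rows = []
        eig_rows = []
        for chrom in chrom_sizes.host_contigs:
            if bins.chromosome_mask(chrom).sum() < 4:
                continue
            try:
                ref_prof = compartment_profile(bins, sorted(groups[ref_cond]), chrom)
            except ValueError as exc:
                manifest.warnings.append(f"compartments {chrom}: {exc}")
                continue
            for st, ev in zip(ref_prof.bin_starts, ref_prof.eigenvector):
                eig_rows.append((chrom, int(st), ref_cond, float(ev)))
            for cond in sorted(g for g in groups if g != ref_cond):
                try:
                    prof = compartment_profile(bins, sorted(groups[cond]), chrom)
                except ValueError as exc:
                    manifest.warnings.append(f"compartments {chrom}/{cond}: {exc}")
                    continue
                score = compartment_dissimilarity(ref_prof, prof)
                rows.append((chrom, cond, ref_cond, score.score, score.n_bins))
                for st, ev in zip(prof.bin_starts, prof.eigenvector):
                    eig_rows.append((chrom, int(st), cond, float(ev)))
        diss_path = out / "compartment_dissimilarity.tsv"
        pd.DataFrame(rows, columns=["chrom", "group", "reference", "score", "n_bins"]).to_csv(
            diss_path, sep="\t", index=False
        )
        eig_path = out / "compartment_eigenvectors.tsv"
        pd.DataFrame(eig_rows, columns=["chrom", "bin_start", "group", "eigenvector"]).to_csv(
            eig_path, sep="\t", index=False
        )
        manifest.record(
            "compartments",
            {"dissimilarity": diss_path, "eigenvectors": eig_path},
            n_compartment_scores=len(rows),
        )

    # --- stage: states ------------------------------------------------------
    st = cfg["states"]
    if st["enabled"]:
        super_map = load_super_state_map(st["map"])
        if st["simulate"]:
            segs = simulate_segmentations(
                {c_: chrom_sizes[c_] for c_ in chrom_sizes.host_contigs},
                n_samples=int(st.get("n_patients", 19)),
                labels_18=sorted(super_map.mapping),
                seed=seed + 1,
            )
        else:
            from .genomic_io import read_segmentations

            segs = read_segmentations(st["segmentations"])
        collapsed = collapse_states(segs, super_map)
        consensus = call_consensus(collapsed, min_fraction=float(st["min_fraction"]))
        cons_path = out / "consensus_states.bed"
        consensus.to_frame().to_csv(cons_path, sep="\t", index=False, header=False)
        up = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for _, r in clusters[clusters["trend"] == "up"].iterrows()
        ]
        down = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for _, r in clusters[clusters["trend"] == "down"].iterrows()
        ]
        comp = state_composition(up, down, consensus)
        comp_path = out / "state_composition.tsv"
        comp.table.to_csv(comp_path, sep="\t", index=False)
        manifest.record(
            "states",
            {"consensus": cons_path, "composition": comp_path},
            n_consensus_intervals=len(consensus.intervals),
        )
    else:
        manifest.stages.append({"stage": "states", "skipped": True})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    log.info("pipeline complete: %s", out)
    return manifest


_ = fragments_to_frames  # re-exported convenience


@dataclass
class AnalysisResult:
    """In-memory result bundle from :func:`analyze_experiment`."""

    counts: Any
    retained: Any
    factors: Any
    offsets: Any
    window_test: Any
    clusters: pd.DataFrame
    design: Any
    dispersions: Any


def analyze_experiment(
    fragments: dict[str, pd.DataFrame],
    chrom_sizes,
    conditions: dict[str, str],
    max_fragment: int = 500,
    background_bin: int = 1000,
    min_fold: float = 3.0,
    spike_tile: int | None = 5000,
    use_ruv: bool = True,
    ruv_k: int = 1,
    use_pc1: bool = False,
    max_gap: int = 100,
    max_width: int = 5000,
    fold: float = 1.5,
    q_threshold: float = 0.05,
    blacklist=(),
) -> AnalysisResult:
    """Count -> filter -> normalize -> test -> cluster, all in memory.

    The file-writing :func:`run_pipeline` wraps the same steps; this entry
    point returns the intermediate objects for programmatic use.
    """
    samples = sorted(conditions)
    grid = tile_windows(chrom_sizes, spike_tile=spike_tile)
    counts = count_fragments(fragments, grid, max_fragment=max_fragment, sample_order=samples)
    counts, _ = apply_blacklist(counts, list(blacklist))
    background = estimate_background(
        fragments, chrom_sizes, background_bin, blacklist=list(blacklist), sample_order=samples
    )
    retention = filter_by_background(counts, background, min_fold=min_fold)
    counts.retained = retention.retained
    controls = build_spike_controls(counts)
    factors = estimate_ruv_factors(counts, controls, k=ruv_k)
    offsets = compute_offsets(counts, factors, mode="ruv" if use_ruv else "library_size")
    covs = []
    names = []
    if use_ruv:
        covs.append(factors.W)
        names += [f"ruv{i + 1}" for i in range(factors.k)]
    if use_pc1:
        covs.append(compute_pc1_covariate(counts)[:, None])
        names.append("pc1")
    covariates = np.hstack(covs) if covs else None
    design = build_design(
        samples, [conditions[s] for s in samples],
        covariates=covariates, covariate_names=names or None,
    )
    retained = counts.subset_rows(retention.retained)
    disp = estimate_dispersions(retained.counts, design, offsets.log_library)
    wtest = test_windows(retained.counts, design, offsets.log_library, disp)
    cids = cluster_windows(
        retained.chroms, retained.starts, retained.ends,
        max_gap=max_gap, max_width=max_width,
    )
    clusters = combine_simes(wtest, cids, retained.chroms, retained.starts, retained.ends)
    if {"logfc_cond_t8", "logfc_cond_t18"} <= set(clusters.columns):
        clusters = classify_trend(clusters, fold=fold, q_threshold=q_threshold)
    return AnalysisResult(
        counts=counts, retained=retained, factors=factors, offsets=offsets,
        window_test=wtest, clusters=clusters, design=design, dispersions=disp,
    )
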