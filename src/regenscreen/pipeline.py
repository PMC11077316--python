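"""Pipeline orchestration: synthesize -> screen -> trees -> tfbs -> expr.

One YAML config drives all stages; a single global seed fans out to
stage-specific derived seeds (stage-name-salted, so adding or removing a
stage does not perturb its siblings), and a JSON manifest records inputs,
outputs (with SHA-256 hashes), parameters and wall times. Reruns with an
identical config and seed reproduce byte-identical primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .expression import classify_matrix, normalize, write_fpkm_tsv
from .screen import ScreenConfig, run_screen
from .similarity import Proteome, ScoringScheme
from .synthetic import (
    HOMEO_CONSENSUS,
    default_species_specs,
    simulate_expression,
    simulate_promoters,
    simulate_pwm_panel,
    simulate_species_set,
    write_scenario,
)
from .tfbs import (
    ScanParams,
    compile_top_classes,
    enrichment_test,
    plot_class_tally,
    records_to_frame,
    scan_gene_set,
    write_class_annotation,
    write_jaspar,
)
from .trees import bootstrap_supports, is_separated_cluster, progressive_align, write_newick

ALL_STAGES = ("simulate", "screen", "tree", "tfbs", "expr")


class ConfigError(ValueError):
    """Aggregated configuration problems; one message per line."""


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seed: int = 7
    outdir: str = "regenscreen_out"
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic scenario
    n_wbr: int = 3
    n_hra: int = 5
    n_lra: int = 8
    n_confirm: int = 2
    n_background: int = 200
    n_cbr: int = 10
    n_paralog: int = 10
    divergence: float = 0.05
    # optional real data: TSV with species_id, reg_class, fasta_path
    species_table: str | None = None
    # screen thresholds
    evalue_max_loss: float = 1e-4
    score_min_hra: int = 100
    grouping: str = "clique"
    # trees
    n_bootstrap: int = 100
    # tfbs
    windows: tuple[int, ...] = (100, 500, 1000, 3000, 5000, 7500)
    plant_rate_target: float = 0.8
    plant_rate_background: float = 0.1
    n_decoy_pwms: int = 19
    score_fraction_threshold: float = 0.85
    # expression
    noise_sd: float = 0.25
    fc_threshold: float = 1.0

    def stage_seed(self, stage: str) -> int:
        return int((self.seed + zlib.crc32(stage.encode())) % (2**31 - 1))


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config, aggregating all errors."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    errors: list[str] = []
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    for key in raw:
        if key not in known:
            errors.append(f"{key}: unknown config field")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.stages = tuple(cfg.stages)
    cfg.windows = tuple(cfg.windows)
    for s in cfg.stages:
        if s not in ALL_STAGES:
            errors.append(f"stages: unknown stage {s!r}")
    for name in ("n_wbr", "n_hra", "n_lra", "n_confirm", "n_background",
                 "n_cbr", "n_paralog", "n_bootstrap"):
        if getattr(cfg, name) < 0:
            errors.append(f"{name}: must be >= 0")
    if cfg.species_table is None:
        if cfg.n_wbr < 2:
            errors.append("n_wbr: need at least two WBR species")
        if cfg.n_lra < 1:
            errors.append("n_lra: need at least one LRA species")
    if cfg.evalue_max_loss <= 0:
        errors.append("evalue_max_loss: must be positive")
    if cfg.score_min_hra <= 0:
        errors.append("score_min_hra: must be positive")
    if not (0 < cfg.score_fraction_threshold <= 1):
        errors.append("score_fraction_threshold: must lie in (0, 1]")
    wl = list(cfg.windows)
    if wl != sorted(set(wl)) or any(w <= 0 for w in wl):
        errors.append("windows: must be positive and strictly increasing")
    if not (0 <= cfg.plant_rate_background <= cfg.plant_rate_target <= 1):
        errors.append("plant rates: need 0 <= background <= target <= 1")
    if cfg.species_table is not None:
        tpath = Path(cfg.species_table)
        if not tpath.is_file():
            errors.append(f"species_table: file not found: {tpath}")
        else:
            tab = pd.read_csv(tpath, sep="\t")
            need = {"species_id", "reg_class", "fasta_path"}
            if not need <= set(tab.columns):
                errors.append(f"species_table: needs columns {sorted(need)}")
            else:
                dup = tab["species_id"][tab["species_id"].duplicated()]
                for s in dup:
                    errors.append(
                        f"species_table: species {s!r} listed in more than one class row"
                    )
                for _, row in tab.iterrows():
                    if not Path(row["fasta_path"]).is_file():
                        errors.append(
                            f"species_table: fasta for {row['species_id']} not found: "
                            f"{row['fasta_path']}"
                        )
    if errors:
        raise ConfigError("\n".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_species_table(path: str) -> tuple[dict[str, Proteome], ScreenConfig]:
    tab = pd.read_csv(path, sep="\t")
    proteomes: dict[str, Proteome] = {}
    lists: dict[str, list[str]] = {"WBR": [], "HRA": [], "LRA": [], "CONFIRM": []}
    for _, row in tab.iterrows():
        p = Proteome.read_fasta(row["fasta_path"], reg_class=row["reg_class"],
                                species_id=row["species_id"])
        proteomes[p.species_id] = p
        lists[row["reg_class"]].append(row["species_id"])
    config = ScreenConfig(
        wbr=tuple(lists["WBR"]), hra=tuple(lists["HRA"]),
        lra=tuple(lists["LRA"]), confirm=tuple(lists["CONFIRM"]),
    )
    return proteomes, config


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "regenscreen",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in config.__dict__.items()},
        "stages": {},
    }
    state: dict[str, Any] = {}
    scheme = ScoringScheme()

    stage_fns = {
        "simulate": _stage_simulate,
        "screen": _stage_screen,
        "tree": _stage_tree,
        "tfbs": _stage_tfbs,
        "expr": _stage_expr,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            outputs = stage_fns[stage](config, outdir, state, scheme)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "completed",
            "seed": config.stage_seed(stage),
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        }
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: Mapping[str, Any], outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, outdir: Path, state: dict, scheme) -> list[Path]:
    specs = default_species_specs(
        config.n_wbr, config.n_hra, config.n_lra, config.n_confirm,
        config.n_background, config.divergence,
    )
    proteomes, truth = simulate_species_set(
        specs, config.n_cbr, config.n_paralog, seed=config.stage_seed("simulate")
    )
    state["proteomes"] = proteomes
    state["truth"] = truth
    state["specs"] = specs
    return write_scenario(outdir / "scenario", proteomes, truth)


def _resolve_proteomes(config: RunConfig, state: dict) -> tuple[dict[str, Proteome], ScreenConfig]:
    if config.species_table is not None:
        return _load_species_table(config.species_table)
    if "proteomes" not in state:
        # screen without a prior simulate stage: regenerate deterministically
        _stage_simulate(config, Path(config.outdir), state, None)
    proteomes = state["proteomes"]
    specs = state["specs"]
    lists = {c: tuple(s.species_id for s in specs if s.reg_class == c)
             for c in ("WBR", "HRA", "LRA", "CONFIRM")}
    screen_cfg = ScreenConfig(
        wbr=lists["WBR"], hra=lists["HRA"], lra=lists["LRA"], confirm=lists["CONFIRM"],
        evalue_max_loss=config.evalue_max_loss, score_min_hra=config.score_min_hra,
        grouping=config.grouping,
    )
    return proteomes, screen_cfg


def _stage_screen(config: RunConfig, outdir: Path, state: dict, scheme) -> list[Path]:
    proteomes, screen_cfg = _resolve_proteomes(config, state)
    result = run_screen(proteomes, screen_cfg, scheme)
    state["screen_result"] = result
    state["screen_config"] = screen_cfg
    return result.write_outputs(outdir / "screen")


def _stage_tree(config: RunConfig, outdir: Path, state: dict, scheme) -> list[Path]:
    if "truth" not in state:
        _stage_simulate(config, outdir, state, scheme)
    truth = state["truth"]
    proteomes = state["proteomes"]
    tdir = outdir / "trees"
    tdir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("tree")
    rows = []
    paths: list[Path] = []
    # paralog families carry both the high-regenerative orthologs and a
    # diverged LRA copy, which is the paper-style ortholog/paralog question
    for k, fam in enumerate(sorted(truth.paralog_family_ids)):
        seqs = []
        focal = set()
        for sp, prot in sorted(proteomes.items()):
            for gene in (fam, f"{fam}_par"):
                if gene in prot.records:
                    label = f"{sp}|{gene}"
                    # use the canonical (first) isoform for tree building
                    seqs.append((label, prot.records[gene][0][1]))
                    if gene == fam:
                        focal.add(label)
        if len(seqs) < 4 or not (0 < len(focal) < len(seqs)):
            continue
        msa = progressive_align(seqs, scheme)
        tree = bootstrap_supports(msa, config.n_bootstrap, seed=seed + k, scheme=scheme)
        npath = tdir / f"{fam}.nwk"
        write_newick(tree, npath)
        paths.append(npath)
        rows.append((fam, len(seqs), is_separated_cluster(tree, focal)))
    summary = pd.DataFrame(rows, columns=["family_id", "n_taxa", "high_regen_separated"])
    spath = tdir / "cluster_separation.tsv"
    summary.to_csv(spath, sep="\t", index=False)
    paths.append(spath)
    state["tree_summary"] = summary
    return paths


def _stage_tfbs(config: RunConfig, outdir: Path, state: dict, scheme) -> list[Path]:
    if "truth" not in state:
        _stage_simulate(config, outdir, state, scheme)
    truth = state["truth"]
    tdir = outdir / "tfbs"
    tdir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("tfbs")
    panel = simulate_pwm_panel(config.n_decoy_pwms, seed=seed)
    ppath = tdir / "pwm_panel.jaspar"
    write_jaspar(panel, ppath)
    cpath = tdir / "pwm_classes.tsv"
    write_class_annotation(panel, cpath)
    params = ScanParams(
        score_fraction_threshold=config.score_fraction_threshold,
        window_lengths=config.windows,
    )
    targets = sorted(truth.motif_target_gene_ids)
    background = sorted(truth.background_family_ids)
    records = []
    for wi, L in enumerate(config.windows):
        promoters, _ = simulate_promoters(
            targets + background, targets, HOMEO_CONSENSUS,
            config.plant_rate_target, config.plant_rate_background, L,
            seed=seed + 1 + wi,
        )
        for pwm in panel:
            hits = scan_gene_set(pwm, promoters, params)
            records.append(
                enrichment_test(set(targets), set(background), hits, pwm, L)
            )
    frame = records_to_frame(records)
    epath = tdir / "enrichment.tsv"
    frame.to_csv(epath, sep="\t", index=False)
    tally = compile_top_classes(records, top_k=10)
    tpath = tdir / "class_tally.tsv"
    tally.to_csv(tpath, sep="\t")
    hpath = tdir / "class_tally.png"
    plot_class_tally(tally, hpath)
    state["tfbs_tally"] = tally
    return [ppath, cpath, epath, tpath, hpath]


def _stage_expr(config: RunConfig, outdir: Path, state: dict, scheme) -> list[Path]:
    if "truth" not in state:
        _stage_simulate(config, outdir, state, scheme)
    truth = state["truth"]
    edir = outdir / "expression"
    edir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("expr")
    phase_by_gene = dict(truth.expression_phase_by_gene)
    # stem-cell marker style contrast genes plus a flat background sample
    for i in range(1, 4):
        phase_by_gene[f"CONTRAST{i}"] = "proliferative"
    for fam in sorted(truth.background_family_ids)[:20]:
        phase_by_gene[fam] = "flat"
    matrix = simulate_expression(phase_by_gene, noise_sd=config.noise_sd, seed=seed)
    fpath = edir / "fpkm.tsv"
    write_fpkm_tsv(matrix, fpath)
    npath = edir / "fpkm_normalized.tsv"
    write_fpkm_tsv(normalize(matrix), npath)
    calls = classify_matrix(matrix, fc_threshold=config.fc_threshold)
    calls["true_phase"] = [phase_by_gene[g] for g in calls.index]
    cpath = edir / "phase_calls.tsv"
    calls.to_csv(cpath, sep="\t")
    state["phase_calls"] = calls
    return [fpath, npath, cpath]
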