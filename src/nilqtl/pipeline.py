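"""End-to-end orchestration: simulate -> kinetics -> validate -> scan -> annotate.

Each stage reads only declared files from the previous stage, is seeded from
a single top-level seed through ``numpy.random.SeedSequence`` spawning, and
records its outputs (with SHA-256 checksums and row counts) in a JSON run
manifest. Re-running with an unchanged config and seed skips stages whose
recorded checksums still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, core_io, effects, kinetics, linkage, markers, simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "kinetics", "validate", "scan", "annotate")


@dataclass
class PipelineConfig:
    seed: int = 42
    n_segregants: int = 77
    n_markers_per_chromosome: int = 3
    n_backcrosses: int = 4
    qtls: list[dict] = field(
        default_factory=lambda: [
            {"marker": "VIII_281", "effect": -8.0, "allele": "B"},
            {"marker": "IV_766", "effect": -10.0, "allele": "B"},
        ]
    )
    trait: str = "RS"
    trait_mean: float = 30.0
    residual_sd: float = 5.0
    n_replicates: int = 2
    n_permutations: int = 1000
    levels: tuple[float, float] = (0.05, 0.10)
    # marker-validation demo inputs
    n_snps: int = 4000
    common_fraction: float = 0.8
    tiling_fdr: float = 0.65
    tiling_jitter_sd: float = 3.0
    match_window: int = 20
    # annotation demo
    annotate_variants: list[str] = field(default_factory=lambda: ["c.4_5delTC"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.n_segregants < 10:
            raise ValueError("n_segregants must be >= 10")
        if not 0 <= self.tiling_fdr < 1:
            raise ValueError("tiling_fdr must be in [0, 1)")
        for q in self.qtls:
            if not {"marker", "effect"} <= set(q):
                raise ValueError("each qtl needs 'marker' and 'effect'")

    def content_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _demo_cds(rng: np.random.Generator, n_codons: int = 120) -> str:
    """A random ORF with no internal stop, used by the annotate demo stage."""
    codons = []
    bases = "ACGT"
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon in ("TAA", "TAG", "TGA"):
            continue
        codons.append(codon)
    return "ATG" + "".join(codons[1:]) + "TAA"


class PipelineRun:
    """A materialized pipeline run under an output directory."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        root = np.random.SeedSequence(config.seed)
        children = root.spawn(len(STAGES))
        self.stage_seeds = {
            stage: int(child.generate_state(1)[0]) for stage, child in zip(STAGES, children)
        }
        self.manifest: dict = {
            "version": __version__,
            "config": dict(config.__dict__),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "stage_seeds": self.stage_seeds,
            "stages": {},
        }

    # -- manifest helpers ---------------------------------------------------

    def _record(self, stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        self.manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {name: _sha256(p) for name, p in files.items()},
            "row_counts": counts,
        }

    def _previous_manifest(self) -> Optional[dict]:
        path = self.out / "manifest.json"
        if not path.exists():
            return None
        try:
            return json.loads(path.read_text())
        except json.JSONDecodeError:
            return None

    def _can_skip(self, stage: str, previous: Optional[dict]) -> bool:
        if previous is None or previous.get("config_hash") != self.manifest["config_hash"]:
            return False
        entry = previous.get("stages", {}).get(stage)
        if not entry or entry.get("status") != "ok":
            return False
        for name, checksum in entry["outputs"].items():
            path = self.out / name
            if not path.exists() or _sha256(path) != checksum:
                return False
        self.manifest["stages"][stage] = entry
        return True

    def _write_manifest(self) -> None:
        (self.out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str) + "\n"
        )

    # -- stages -------------------------------------------------------------

    def run(self, resume: bool = True) -> Path:
        previous = self._previous_manifest() if resume else None
        t0 = time.time()
        try:
            for stage in STAGES:
                if self._can_skip(stage, previous):
                    log.info("stage %s: outputs up to date, skipping", stage)
                    continue
                log.info("stage %s: running", stage)
                getattr(self, f"_stage_{stage}")()
        except Exception:
            self.manifest["stages"].setdefault(stage, {})["status"] = "failed"
            self._write_manifest()
            raise
        self.manifest["elapsed_s"] = round(time.time() - t0, 2)
        self._write_manifest()
        return self.out / "manifest.json"

    def _sim_config(self) -> simulate.SimulationConfig:
        cfg = self.config
        return simulate.SimulationConfig(
            seed=self.stage_seeds["simulate"],
            n_markers_per_chromosome=cfg.n_markers_per_chromosome,
            n_backcrosses=cfg.n_backcrosses,
            n_segregants=cfg.n_segregants,
            qtls=[
                simulate.QtlSpec(q["marker"], float(q["effect"]), q.get("allele", "B"))
                for q in cfg.qtls
            ],
            trait_mean=cfg.trait_mean,
            residual_sd=cfg.residual_sd,
            n_replicates=cfg.n_replicates,
            n_snps=cfg.n_snps,
            common_fraction=cfg.common_fraction,
            trait=cfg.trait,
        )

    def _stage_simulate(self) -> None:
        sim_cfg = self._sim_config()
        panel, matrix, pheno = simulate.simulate_population(sim_cfg)
        files = {
            "panel.tsv": self.out / "panel.tsv",
            "genotypes.tsv": self.out / "genotypes.tsv",
            "phenotypes.tsv": self.out / "phenotypes.tsv",
        }
        core_io.write_marker_panel(panel, files["panel.tsv"])
        core_io.write_genotype_matrix(matrix, files["genotypes.tsv"])
        core_io.write_phenotype_table(pheno, files["phenotypes.tsv"])
        self._record(
            "simulate",
            files,
            {
                "markers": len(panel),
                "segregants": len(matrix.segregants),
                "phenotype_rows": len(pheno.frame),
            },
        )

    def _stage_kinetics(self) -> None:
        """Simulate one CO2 curve per segregant (slower fermentations for
        higher residual sugar) and extract the kinetic trait panel."""
        rng = np.random.default_rng(self.stage_seeds["kinetics"])
        pheno = core_io.read_phenotype_table(self.out / "phenotypes.tsv")
        rs = pheno.trait_means(self.config.trait)
        curves = []
        for seg, value in rs.items():
            params = simulate.KineticModelParams(
                co2_max=max(120.0 - value, 60.0),
                t_mid=60.0 + 0.8 * value,
                k=0.06,
                noise_sd=1.0,
                times=np.arange(0.0, 240.0, 4.0),
            )
            curves.append(simulate.simulate_co2_curve(params, rng=rng, meta={"segregant": seg}))
        table = kinetics.traits_table(curves)
        path = self.out / "kinetic_traits.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.4f")
        self._record("kinetics", {"kinetic_traits.tsv": path}, {"curves": len(curves)})

    def _stage_validate(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(self.stage_seeds["validate"])
        sim_cfg = self._sim_config()
        b_snps, g_snps, truth_panel = simulate.simulate_parental_snp_sets(sim_cfg, rng=rng)
        positions = [m.position for m in truth_panel]
        predictions = simulate.simulate_tiling_predictions(
            positions,
            sim_cfg.chromosomes,
            jitter_sd=cfg.tiling_jitter_sd,
            false_positive_rate=cfg.tiling_fdr,
            rng=rng,
        )
        pred_records = [
            markers.PredictionRecord(
                position=core_io.GenomePosition(row.chrom, int(row.pos)),
                peak_z=float(row.z),
                span_start=int(row.pos),
                span_end=int(row.pos),
            )
            for row in predictions.itertuples()
        ]
        wgs = markers.filter_wgs_snps(b_snps) + markers.filter_wgs_snps(g_snps)
        report = markers.match_predictions(pred_records, wgs, window=cfg.match_window)
        validated = markers.assign_parental_origin(
            [s.position for _, s, _ in report.matches], b_snps, g_snps
        )
        files = {
            "tiling_predictions.tsv": self.out / "tiling_predictions.tsv",
            "match_report.json": self.out / "match_report.json",
            "validated_panel.tsv": self.out / "validated_panel.tsv",
        }
        predictions.to_csv(files["tiling_predictions.tsv"], sep="\t", index=False)
        files["match_report.json"].write_text(json.dumps(report.summary(), indent=2) + "\n")
        core_io.write_marker_panel(validated, files["validated_panel.tsv"])
        self._record(
            "validate",
            files,
            {"predictions": report.n_predicted, "validated": len(validated)},
        )

    def _stage_scan(self) -> None:
        cfg = self.config
        matrix = core_io.read_genotype_matrix(self.out / "genotypes.tsv")
        pheno = core_io.read_phenotype_table(self.out / "phenotypes.tsv")
        panel = core_io.read_marker_panel(self.out / "panel.tsv")
        qc = linkage.qc_genotypes(matrix)
        result = linkage.scan_with_thresholds(
            matrix,
            pheno,
            cfg.trait,
            n_perm=cfg.n_permutations,
            levels=cfg.levels,
            seed=self.stage_seeds["scan"],
            panel=panel,
        )
        files = {"scan.tsv": self.out / "scan.tsv", "qc.json": self.out / "qc.json"}
        core_io.write_linkage_table(result, files["scan.tsv"])
        files["qc.json"].write_text(
            json.dumps(
                {
                    "call_rate": qc.call_rate,
                    "n_markers": int(len(qc.per_marker)),
                    "n_distorted": int((~qc.per_marker["passed"]).sum()),
                    "thresholds": {str(k): v for k, v in result.thresholds.items()},
                },
                indent=2,
            )
            + "\n"
        )
        self._record(
            "scan",
            files,
            {"scanned_markers": len(result.table),
             "significant5": int(len(result.significant(0.05)))},
        )

    def _stage_annotate(self) -> None:
        rng = np.random.default_rng(self.stage_seeds["annotate"])
        cds = _demo_cds(rng)
        rows = []
        for notation in self.config.annotate_variants:
            try:
                cons = effects.consequence(cds, notation)
            except ValueError as exc:  # ref mismatch against the demo ORF
                log.warning("variant %s not applicable to demo CDS: %s", notation, exc)
                continue
            rows.append(
                {
                    "variant": notation,
                    "class": cons.category,
                    "p_notation": cons.p_notation,
                    "mutant_length": cons.mutant_length,
                    "reference_length": cons.reference_length,
                }
            )
        path = self.out / "consequences.tsv"
        pd.DataFrame(
            rows,
            columns=["variant", "class", "p_notation", "mutant_length", "reference_length"],
        ).to_csv(path, sep="\t", index=False)
        (self.out / "demo_cds.fasta").write_text(f">demo_cds\n{cds}\n")
        self._record(
            "annotate",
            {"consequences.tsv": path, "demo_cds.fasta": self.out / "demo_cds.fasta"},
            {"variants": len(rows)},
        )


def run_pipeline(config_path: str | Path, out_dir: str | Path,
                 seed: Optional[int] = None, resume: bool = True) -> Path:
    """Run the full pipeline from a YAML config; returns the manifest path."""
    config = PipelineConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = seed
    return PipelineRun(config, out_dir).run(resume=resume)
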