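"""End-to-end atlas runs: configuration, stage wiring, manifest.

A :class:`PipelineConfig` names the stages to run and their parameters;
:func:`run_atlas` executes them in dependency order (simulate -> profile ->
digest/LUMA -> bisulfite -> repertoire -> expression), writes TSV/JSON
outputs under the output directory, and records every artifact in a
manifest. Runs are deterministic: identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bisulfite as bs
from . import cpg_profile as cp
from . import expression as ex
from . import repertoire as rp
from . import restriction_luma as rl
from . import synthdata as sd

__all__ = ["PipelineConfig", "DependencyError", "run_atlas", "write_fasta", "read_fasta"]

_STAGES = ("transcriptome", "luma", "bisulfite", "repertoire", "expression")


class DependencyError(RuntimeError):
    """A stage is missing an upstream artifact it needs."""


@dataclass
class PipelineConfig:
    """Global seed plus one optional parameter block per stage.

    Unknown stage names or parameter keys are rejected at construction so a
    typo never silently disables a stage.
    """

    seed: int = 0
    out_dir: str = "atlas_out"
    log_level: str = "INFO"
    stages: dict = field(default_factory=dict)

    _STAGE_KEYS = {
        "transcriptome": {"n", "length_min", "length_max", "gc", "target_oe", "min_len", "n_boot"},
        "luma": {"genome_length", "n_ccgg", "n_ecori", "gc", "fraction", "noise_cv", "replicates", "simulate", "estimate"},
        "bisulfite": {"locus_length", "gc", "per_cpg_m", "n_reads", "conversion_rate", "error_rate", "replicates"},
        "repertoire": {"tree", "matrix", "node"},
        "expression": {"table", "pairs", "fc_threshold", "low_threshold"},
    }

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage, params in self.stages.items():
            bad = set(params) - self._STAGE_KEYS[stage]
            if bad:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(bad)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def write_fasta(records, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord as BioRecord

    bio = [BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    seqio_write(bio, str(path), "fasta")


def read_fasta(path) -> list:
    from Bio.SeqIO import parse

    return [sd.SequenceRecord(id=r.id, residues=str(r.seq).upper()) for r in parse(str(path), "fasta")]


def _stage_seed(seed: int, stage: str) -> int:
    # distinct stream per stage, kept below 2**31; crc32 is process-stable
    import zlib

    return int(
        np.random.default_rng([seed, zlib.crc32(stage.encode())]).integers(0, 2**31 - 1)
    )


def run_atlas(config: PipelineConfig) -> dict:
    """Run the configured stages and return the manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }

    def register(path: Path) -> str:
        manifest["outputs"].append(str(path))
        return str(path)

    if "transcriptome" in config.stages:
        p = config.stages["transcriptome"]
        seed = _stage_seed(config.seed, "transcriptome")
        seqs = sd.simulate_transcriptome(
            n=p.get("n", 5000),
            length_range=(p.get("length_min", 500), p.get("length_max", 3000)),
            gc=p.get("gc", 0.4),
            target_oe=p.get("target_oe", 0.55),
            seed=seed,
        )
        fasta = out / "transcriptome.fasta"
        write_fasta(seqs, fasta)
        register(fasta)
        dist = cp.profile_sequences(
            seqs, min_len=p.get("min_len", 200), n_boot=p.get("n_boot", 1000), seed=seed
        )
        call = cp.classify_methylation_type(dist)
        stats = [cp.cpg_oe(s) for s in seqs]
        tsv = out / "cpg_oe.tsv"
        pd.DataFrame(
            [(s.seq_id, s.n_cpg, s.n_c, s.n_g, s.l_eff, s.oe) for s in stats],
            columns=["seq_id", "n_cpg", "n_c", "n_g", "l_eff", "oe"],
        ).to_csv(tsv, sep="\t", index=False)
        register(tsv)
        summary = {
            "n_sequences": len(dist.values),
            "mean_oe": dist.mean,
            "ci95": list(dist.ci),
            "modes": [dataclasses.asdict(m) for m in dist.modes],
            "methylation_type": call.type,
            "rule_trace": call.rule_trace,
            "seed": seed,
        }
        js = out / "cpg_profile.json"
        js.write_text(json.dumps(summary, indent=2, sort_keys=True))
        register(js)
        manifest["stages"]["transcriptome"] = summary

    if "luma" in config.stages:
        p = config.stages["luma"]
        seed = _stage_seed(config.seed, "luma")
        if not p.get("simulate", True) and p.get("estimate", True):
            raise DependencyError(
                "stage 'luma': estimate requested but no pyrograms available "
                "(simulate disabled and no pyrogram inputs configured)"
            )
        genome = sd.simulate_genome_with_sites(
            length=p.get("genome_length", 200_000),
            n_ccgg=p.get("n_ccgg", 300),
            n_ecori=p.get("n_ecori", 150),
            gc=p.get("gc", 0.4),
            seed=seed,
        )
        methylome = sd.assign_ccgg_methylation(genome, p.get("fraction", 0.8), seed=seed + 1)
        mt = out / "methylome.tsv"
        pd.DataFrame(
            {"position": methylome.site_positions, "methylated": [int(b) for b in methylome.methylated]}
        ).to_csv(mt, sep="\t", index=False)
        register(mt)
        mean_pct, reps = rl.estimate_percent_methylation(
            genome,
            methylome,
            noise_cv=p.get("noise_cv", 0.0),
            n_replicates=p.get("replicates", 1),
            seed=seed,
        )
        luma = {
            "percent_methylation_mean": mean_pct,
            "replicates": [dataclasses.asdict(r) for r in reps],
            "true_fraction": p.get("fraction", 0.8),
            "n_ccgg": genome.declared_ccgg_count,
            "n_ecori": genome.declared_ecori_count,
            "seed": seed,
        }
        js = out / "luma.json"
        js.write_text(json.dumps(luma, indent=2, sort_keys=True))
        register(js)
        manifest["stages"]["luma"] = {"percent_methylation_mean": mean_pct}

    if "bisulfite" in config.stages:
        p = config.stages["bisulfite"]
        seed = _stage_seed(config.seed, "bisulfite")
        rng = np.random.default_rng(seed)
        locus = _locus_with_cpgs(p.get("locus_length", 200), p.get("gc", 0.5), rng)
        n_cpg = locus.residues.count("CG")
        per_m = p.get("per_cpg_m") or [0.8] * n_cpg
        profiles = []
        for rep in range(p.get("replicates", 2)):
            reads = sd.simulate_bisulfite_reads(
                locus,
                per_m,
                n_reads=p.get("n_reads", 500),
                conversion_rate=p.get("conversion_rate", 0.98),
                error_rate=p.get("error_rate", 0.001),
                seed=seed + 10 + rep,
            )
            profiles.append(bs.quantify_methylation(reads))
        summary = bs.aggregate_replicates(profiles)
        tsv = out / "bisulfite.tsv"
        pd.DataFrame(
            {"position": summary.cpg_positions, "mean_percent": summary.mean, "sd": summary.sd}
        ).to_csv(tsv, sep="\t", index=False)
        register(tsv)
        manifest["stages"]["bisulfite"] = {
            "n_cpg": n_cpg,
            "n_replicates": summary.n_replicates,
            "conversion_qc": profiles[0].conversion_qc,
        }

    if "repertoire" in config.stages:
        p = config.stages["repertoire"]
        tree = rp.load_tree(p["tree"]) if "tree" in p else rp.demo_metazoan_tree()
        matrix = rp.load_matrix(p["matrix"]) if "matrix" in p else rp.demo_metazoan_matrix()
        node = p.get("node", "Metazoa")
        ancestral = rp.ancestral_repertoire(tree, matrix, node)
        summary_df = rp.repertoire_summary(matrix)
        tsv = out / "repertoire_summary.tsv"
        summary_df.to_csv(tsv, sep="\t", index_label="species")
        register(tsv)
        js = out / "ancestral_repertoire.json"
        js.write_text(
            json.dumps({"node": node, "present_families": sorted(ancestral)}, indent=2)
        )
        register(js)
        manifest["stages"]["repertoire"] = {
            "node": node,
            "n_ancestral_families": len(ancestral),
        }

    if "expression" in config.stages:
        p = config.stages["expression"]
        if "table" not in p:
            raise DependencyError("stage 'expression': no FPKM table configured")
        table = ex.load_expression_table(p["table"])
        pairs = p.get("pairs") or [
            (str(a), str(b)) for a, b in zip(table.columns, table.columns[1:])
        ]
        pairs = [tuple(pr) for pr in pairs]
        summary = ex.transition_summary(
            table,
            pairs,
            fc_threshold=p.get("fc_threshold", 2.0),
            low_threshold=p.get("low_threshold", 5.0),
        )
        tsv = out / "transitions.tsv"
        summary.assign(
            low_expression_genes=summary["low_expression_genes"].map(",".join)
        ).to_csv(tsv, sep="\t", index=False)
        register(tsv)
        manifest["stages"]["expression"] = {"n_pairs": len(pairs)}

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _locus_with_cpgs(length: int, gc: float, rng: np.random.Generator):
    """Random locus guaranteed to contain at least one CpG."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for _ in range(100):
        arr = rng.choice(list("ACGT"), size=length, p=p)
        seq = "".join(arr)
        if "CG" in seq:
            return sd.SequenceRecord(id="locus", residues=seq)
    raise RuntimeError("failed to draw a locus containing a CpG")
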