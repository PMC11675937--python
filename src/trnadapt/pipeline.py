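"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (reference -> quantification -> codon usage
-> optimality metrics -> multivariate), every output is a plain TSV with a
provenance header (version, config hash, seed), and any stage failure
aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .codons import (
    aa_normalized_frequencies,
    codon_count_matrix,
    normalized_frequencies,
    read_cds_fasta,
)
from .multivariate import kmeans_elbow, pca_codon_usage
from .optimality import CodonOptimalityModel
from .quant import (
    aggregate_isoacceptors,
    condition_fold_change,
    condition_means,
    normalize_counts,
    tmm_factors,
)
from .reference import (
    build_isodecoder_reference,
    build_isoacceptor_map,
    parse_trna_fasta,
    write_reference_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_scenario", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated inputs and thresholds for a full run."""

    trna_fasta: str
    counts_tsv: str
    samples_tsv: str
    cds_fasta: str
    half_life_tsv: str
    expression_tsv: str
    reference_cds_fasta: str
    condition_a: str
    condition_b: str
    out_dir: str
    lfc_threshold: float = 0.5
    csc_pos_threshold: float = 0.01
    csc_neg_threshold: float = -0.01
    content_min_percent: float = 2.0
    delta_tai_threshold: float = 0.2
    top_fraction: float = 0.10
    scale: float = 1e6
    k_range: tuple[int, int] = (2, 8)
    n_restarts: int = 10
    seed: int = 0
    # measured tRNA sets rarely cover every codon's cognates; substitute the
    # smallest positive tAI for undecodable codons instead of aborting
    zero_policy: str = "floor"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in (
            "trna_fasta",
            "counts_tsv",
            "samples_tsv",
            "cds_fasta",
            "half_life_tsv",
            "expression_tsv",
            "reference_cds_fasta",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.condition_a == self.condition_b:
            raise ValueError("condition_a and condition_b must differ")
        self.k_range = tuple(self.k_range)  # yaml gives a list

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# trnadapt {__version__} config={cfg.content_hash()} "
            f"seed={cfg.seed}\n"
        )
        df.to_csv(fh, sep="\t")


def write_scenario(scn, out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Write a synthetic scenario as pipeline input files plus a config.

    ``scn`` is a :class:`trnadapt.simulate.Scenario`. Returns a ready
    :class:`PipelineConfig` pointing at the written files.
    """
    from .simulate import write_trna_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trna_fasta(scn.trna_genes, out / "trna_genes.fasta")
    scn.counts.to_csv(out / "counts.tsv", sep="\t")
    samples = pd.DataFrame(
        {
            "condition": scn.sample_conditions,
            "replicate": [
                int(s.rsplit("_", 1)[-1]) for s in scn.sample_conditions.index
            ],
        }
    )
    samples.index.name = "sample_id"
    samples.to_csv(out / "samples.tsv", sep="\t")
    with open(out / "cds.fasta", "w") as fh:
        for g, seq in scn.cds.items():
            fh.write(f">{g}\n{seq}\n")
    with open(out / "reference_cds.fasta", "w") as fh:
        for g, seq in scn.reference_cds.items():
            fh.write(f">{g}\n{seq}\n")
    scn.half_lives.rename_axis("gene_id").to_csv(
        out / "half_lives.tsv", sep="\t"
    )
    scn.expression.rename_axis("gene_id").to_csv(
        out / "expression.tsv", sep="\t"
    )
    scn.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = PipelineConfig(
        trna_fasta=str(out / "trna_genes.fasta"),
        counts_tsv=str(out / "counts.tsv"),
        samples_tsv=str(out / "samples.tsv"),
        cds_fasta=str(out / "cds.fasta"),
        half_life_tsv=str(out / "half_lives.tsv"),
        expression_tsv=str(out / "expression.tsv"),
        reference_cds_fasta=str(out / "reference_cds.fasta"),
        condition_a=scn.conditions[0],
        condition_b=scn.conditions[1],
        out_dir=str(out / "results"),
        seed=seed,
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the in-memory outputs and writes TSVs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    # --- reference ---------------------------------------------------------
    stage = "reference"
    try:
        genes, failures = parse_trna_fasta(config.trna_fasta)
        if failures:
            logger.warning("%d unparsable tRNA headers", len(failures))
        isodecoders = build_isodecoder_reference(genes)
        isoacceptors = build_isoacceptor_map(isodecoders)
        write_reference_fasta(isodecoders, out / "isodecoder_reference.fasta")
        mapping = pd.DataFrame(
            [
                (g, iso.group_id, f"{iso.amino_acid}-{iso.anticodon}")
                for iso in isodecoders
                for g in iso.member_gene_ids
            ],
            columns=["gene_id", "isodecoder_group", "isoacceptor"],
        ).set_index("gene_id")
        _write_tsv(mapping, out / "reference_map.tsv", config)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- quantification ----------------------------------------------------
    stage = "quantify"
    try:
        counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(config.samples_tsv, sep="\t", index_col=0)
        sample_conditions = samples["condition"].to_dict()
        factors = tmm_factors(counts)
        abundance = normalize_counts(counts, factors, scale=config.scale)
        fc = condition_fold_change(
            abundance,
            sample_conditions,
            config.condition_a,
            config.condition_b,
            lfc_threshold=config.lfc_threshold,
        )
        iso_map = {
            f"{iso.amino_acid}-{iso.anticodon}": list(iso.isodecoder_group_ids)
            for iso in isoacceptors
        }
        measured = set(abundance.index)
        iso_map = {
            k: [m for m in v if m in measured] for k, v in iso_map.items()
        }
        iso_map = {k: v for k, v in iso_map.items() if v}
        if not iso_map:
            raise ValueError(
                "no count features match the isodecoder reference"
            )
        mapped = sorted({m for v in iso_map.values() for m in v})
        iso_abundance = aggregate_isoacceptors(abundance.loc[mapped], iso_map)
        pool_means = condition_means(iso_abundance, sample_conditions)
        # anticodon-keyed pool for tAI: drop the initiator (tAI models
        # elongation) and strip the amino-acid prefix
        pool_means = pool_means.loc[
            [k for k in pool_means.index if not k.startswith("iMet-")]
        ]
        pool_means.index = [k.rsplit("-", 1)[-1] for k in pool_means.index]
        _write_tsv(abundance, out / "isodecoder_abundance.tsv", config)
        _write_tsv(fc, out / "isodecoder_fold_change.tsv", config)
        _write_tsv(iso_abundance, out / "isoacceptor_abundance.tsv", config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- codon usage -------------------------------------------------------
    stage = "codons"
    try:
        cds = read_cds_fasta(config.cds_fasta)
        codon_counts = codon_count_matrix(cds)
        freqs = normalized_frequencies(codon_counts)
        aa_norm = aa_normalized_frequencies(codon_counts)
        _write_tsv(codon_counts, out / "codon_counts.tsv", config)
        _write_tsv(freqs, out / "codon_frequencies.tsv", config)
        _write_tsv(aa_norm, out / "codon_frequencies_aa_normalized.tsv", config)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- optimality metrics ------------------------------------------------
    stage = "metrics"
    try:
        half_lives = pd.read_csv(config.half_life_tsv, sep="\t", index_col=0)
        expression = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        reference_cds = read_cds_fasta(config.reference_cds_fasta)
        model = CodonOptimalityModel(
            codon_counts=codon_counts,
            isoacceptor_abundance=pool_means,
            half_lives=half_lives,
            expression=expression,
            reference_counts=codon_count_matrix(reference_cds).sum(axis=0),
            conditions=(config.condition_a, config.condition_b),
            csc_pos_threshold=config.csc_pos_threshold,
            csc_neg_threshold=config.csc_neg_threshold,
            delta_tai_threshold=config.delta_tai_threshold,
            zero_policy=config.zero_policy,
        )
        results = model.fit()
        ranked = results.gene_metrics.sort_values(
            "delta_sdr", ascending=False, kind="mergesort"
        )
        _write_tsv(results.codon_metrics, out / "codon_metrics.tsv", config)
        _write_tsv(results.gene_metrics, out / "gene_metrics.tsv", config)
        _write_tsv(ranked[["delta_sdr"]], out / "delta_sdr_ranked.tsv", config)
        (out / "summary.txt").write_text(results.summary() + "\n")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- multivariate ------------------------------------------------------
    stage = "cluster"
    try:
        usable = aa_norm.loc[results.gene_metrics.index]
        pca = pca_codon_usage(usable, n_components=2)
        clusters = kmeans_elbow(
            usable,
            k_range=config.k_range,
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        _write_tsv(pca.scores, out / "pca_scores.tsv", config)
        _write_tsv(pca.loadings, out / "pca_loadings.tsv", config)
        _write_tsv(
            clusters.labels.to_frame(), out / "cluster_assignments.tsv", config
        )
        _write_tsv(
            clusters.inertia_trace.rename("inertia").to_frame(),
            out / "kmeans_inertia_trace.tsv",
            config,
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    logger.info("pipeline complete: %s", out)
    return {
        "isodecoders": isodecoders,
        "isoacceptors": isoacceptors,
        "fold_change": fc,
        "isoacceptor_abundance": pool_means,
        "results": results,
        "pca": pca,
        "clusters": clusters,
        "out_dir": out,
    }
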