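"""End-to-end analysis pipeline and plot-ready table emission.

``run_pipeline`` ties the modules together: read coding sequences, compute
per-strain composition and ENC, per-strain and pooled RSCU with
representation classes, PCA scores over the strain x 59 RSCU matrix, the
correlation suite, the ENC-vs-GC3 table with the expected-curve column,
and the host-comparison report.  Outputs are plot-ready TSV tables (all
percentages at 2 decimals) plus a full-precision JSON and a machine-
readable run manifest.  Computation happens before any file is written,
so a failing stage aborts with a stage-tagged error and leaves no partial
output behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .codon_stats import (
    classify_representation,
    composition,
    count_codons,
    enc,
    expected_enc,
    rscu,
)
from .genetic_code import CODON_TO_AA, SYNONYMOUS_CODONS
from .host_compare import compare_rscu, comparison_frame, load_host_reference
from .multivariate import build_rscu_matrix, correlation_suite, pca_rscu
from .seqio import CodingSequence, ValidationPolicy, read_fasta, \
    read_genbank_cds

logger = logging.getLogger("codonuse")

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "manifest_accessions", "strain_manifest"]

ARTIFACTS = (
    "composition.tsv",
    "rscu_per_strain.tsv",
    "rscu_pooled.tsv",
    "representation.tsv",
    "strain_summary.tsv",
    "correlations.tsv",
    "enc_gc3.tsv",
    "host_comparison.tsv",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage."""


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs, validated up front."""

    inputs: list[str]
    outdir: str
    input_format: Literal["fasta", "genbank"] = "fasta"
    join_mode: Literal["concatenate-all-cds", "per-cds"] = \
        "concatenate-all-cds"
    policy: ValidationPolicy = dataclasses.field(
        default_factory=ValidationPolicy)
    pca_scaling: Literal["covariance", "correlation"] = "covariance"
    host_reference: str = "human-Table2"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_format not in ("fasta", "genbank"):
            raise ValueError(f"bad input_format: {self.input_format!r}")
        if self.join_mode not in ("concatenate-all-cds", "per-cds"):
            raise ValueError(f"bad join_mode: {self.join_mode!r}")
        if self.pca_scaling not in ("covariance", "correlation"):
            raise ValueError(f"bad pca_scaling: {self.pca_scaling!r}")
        if not self.inputs:
            raise ValueError("no input files given")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with a stage tag."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _read(cfg: RunConfig) -> list[CodingSequence]:
    seqs: list[CodingSequence] = []
    for path in cfg.inputs:
        if cfg.input_format == "fasta":
            seqs.extend(read_fasta(path, cfg.policy))
        else:
            seqs.extend(read_genbank_cds(path, cfg.policy, cfg.join_mode))
    return seqs


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the whole analysis; returns a name -> path map of artifacts."""
    logging.basicConfig(level=cfg.log_level)

    with _stage("read"):
        seqs = _read(cfg)
        ids = [s.id for s in seqs]

    with _stage("count"):
        tables = count_codons(seqs, pool=False)
        if isinstance(tables, list) is False:
            tables = [tables]
        pooled = count_codons(seqs, pool=True)

    with _stage("composition"):
        profiles = [composition(t) for t in tables]
        enc_results = [enc(t) for t in tables]
        comp_rows = []
        for sid, prof, e in zip(ids, profiles, enc_results):
            row = {"id": sid}
            for b in "TCAG":
                row[f"{b}%"] = prof.overall[b]
            for b in "TCAG":
                row[f"{b}3%"] = (prof.third_syn[b]
                                 if prof.third_syn is not None else np.nan)
            row["gc12"] = prof.gc12
            row["gc3"] = prof.gc3 if prof.gc3 is not None else np.nan
            row["enc"] = e.enc if e.enc is not None else np.nan
            comp_rows.append(row)
        comp_df = pd.DataFrame(comp_rows)

    with _stage("rscu"):
        vectors = [rscu(t) for t in tables]
        pooled_vec = rscu(pooled)
        per_strain = pd.DataFrame(
            [[v.values[c] for c in SYNONYMOUS_CODONS] for v in vectors],
            index=ids, columns=list(SYNONYMOUS_CODONS))
        pooled_df = pd.DataFrame({
            "codon": list(SYNONYMOUS_CODONS),
            "amino_acid": [CODON_TO_AA[c] for c in SYNONYMOUS_CODONS],
            "rscu": [pooled_vec.values[c] for c in SYNONYMOUS_CODONS],
        })
        classes = classify_representation(pooled_vec)
        repr_df = pooled_df.assign(
            classification=[classes[c] for c in SYNONYMOUS_CODONS])

    with _stage("pca"):
        if len(seqs) >= 3:
            matrix = build_rscu_matrix(vectors, ids)
            pca = pca_rscu(matrix, scaling=cfg.pca_scaling)
            f1 = pca.coordinates[:, 0]
            f2 = (pca.coordinates[:, 1] if pca.coordinates.shape[1] > 1
                  else np.full(len(ids), np.nan))
            pca_meta = {
                "scaling": cfg.pca_scaling,
                "variance_fraction": (
                    None if pca.variance_fraction is None
                    else [float(v) for v in pca.variance_fraction]),
            }
        else:
            f1 = np.full(len(ids), np.nan)
            f2 = np.full(len(ids), np.nan)
            pca_meta = {"scaling": cfg.pca_scaling,
                        "variance_fraction": None,
                        "note": "fewer than 3 strains; PCA skipped"}
        summary_df = pd.DataFrame({
            "id": ids, "f1_prime": f1, "f2_prime": f2,
            "enc": comp_df["enc"],
        })

    with _stage("correlate"):
        if len(seqs) >= 3:
            report = correlation_suite(
                profiles, enc_values=list(comp_df["enc"]))
            corr_df = pd.DataFrame(
                report.pairs, columns=["x", "y", "r", "p", "n"])
        else:
            corr_df = pd.DataFrame(columns=["x", "y", "r", "p", "n"])

    with _stage("enc_gc3"):
        enc_gc3_df = pd.DataFrame({
            "id": ids,
            "gc3": comp_df["gc3"],
            "enc": comp_df["enc"],
            "expected_enc": [
                expected_enc(g / 100.0) if np.isfinite(g) else np.nan
                for g in comp_df["gc3"]
            ],
        })

    with _stage("host_compare"):
        host = load_host_reference(cfg.host_reference)
        host_df = comparison_frame(compare_rscu(pooled_vec, host))

    with _stage("write"):
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _emit(name: str, df: pd.DataFrame, **kwargs) -> None:
            path = outdir / name
            df.to_csv(path, sep="\t", index=kwargs.get("index", False),
                      float_format="%.2f")
            paths[name] = path

        _emit("composition.tsv", comp_df)
        _emit("rscu_per_strain.tsv", per_strain, index=True)
        _emit("rscu_pooled.tsv", pooled_df)
        _emit("representation.tsv", repr_df)
        _emit("strain_summary.tsv", summary_df)
        _emit("correlations.tsv", corr_df)
        _emit("enc_gc3.tsv", enc_gc3_df)
        _emit("host_comparison.tsv", host_df)

        full = {
            "composition": comp_df.to_dict(orient="records"),
            "strain_summary": summary_df.to_dict(orient="records"),
            "pooled_rscu": pooled_df.to_dict(orient="records"),
            "correlations": corr_df.to_dict(orient="records"),
            "pca": pca_meta,
        }
        results_path = outdir / "results.json"
        results_path.write_text(json.dumps(full, indent=1, sort_keys=True,
                                           allow_nan=True))
        paths["results.json"] = results_path

        manifest = {
            "config": {
                "inputs": list(cfg.inputs),
                "input_format": cfg.input_format,
                "join_mode": cfg.join_mode,
                "policy": dataclasses.asdict(cfg.policy),
                "pca_scaling": cfg.pca_scaling,
                "host_reference": cfg.host_reference,
                "seed": cfg.seed,
            },
            "versions": {"codonuse": __version__,
                         "numpy": np.__version__,
                         "pandas": pd.__version__},
            "n_strains": len(ids),
        }
        manifest_path = outdir / "run_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1,
                                            sort_keys=True))
        paths["run_manifest.json"] = manifest_path

    return paths


def strain_manifest() -> pd.DataFrame:
    """The packaged 58-strain manifest (accession, f1', f2', ENC, flags).

    Reproduced verbatim from its published source, anomalies included: one
    accession appears twice and one is truncated; both are flagged in the
    ``flags`` column.
    """
    with resources.files("codonuse.data").joinpath(
            "hbv_strain_manifest.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"flags": "string"})
    df["flags"] = df["flags"].fillna("")
    return df


def manifest_accessions() -> list[str]:
    """The 58 strain accessions, verbatim (duplicates/truncations kept)."""
    return list(strain_manifest()["accession"])
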