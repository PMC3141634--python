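"""Readers, writers and the end-to-end pipeline.

All tabular data travels as TSV (gene ids in the first column, library
labels in the header), alignments as FASTA, trees as newick. Writers and
readers round-trip losslessly. :func:`run_pipeline` chains
normalization -> R test -> PEG/ubiquitous/stress calls -> entropy profile
-> category enrichment and records a JSON manifest (seed, thresholds,
row counts, output checksums) sufficient to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .enrichment import category_overrepresentation
from .entropy import entropy_profile
from .normalize import library_total_scale, quantile_normalize
from .rates import Alignment, tree_to_newick
from .rtest import (
    PegThresholds,
    call_pegs,
    call_stress_responsive,
    call_ubiquitous,
    r_test_matrix,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_annotation",
    "write_annotation",
    "read_newick",
    "write_newick",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("trexp")


def read_count_table(path) -> pd.DataFrame:
    """Read a gene x library TSV count table with strict validation."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty count table")
    header = lines[0].rstrip("\n").split("\t")
    libraries = header[1:]
    if len(libraries) < 1:
        raise ValueError(f"{path}: header must name at least one library")
    if len(set(libraries)) != len(libraries):
        raise ValueError(f"{path}: duplicate library labels in header")
    genes, rows = [], []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from None
        if any(v < 0 for v in values):
            raise ValueError(f"{path}: line {lineno}: negative count")
        genes.append(gene)
        rows.append(values)
    if not genes:
        raise ValueError(f"{path}: no data rows")
    matrix = pd.DataFrame(rows, index=genes, columns=libraries)
    matrix.index.name = "gene"
    return matrix


def write_count_table(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_fasta_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        offenders = [f"{lab} ({len(s)} nt)" for lab, s in records]
        raise ValueError(f"{path}: unequal sequence lengths: {', '.join(offenders)}")
    return Alignment.from_sequences(records)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label in aln.labels:
            fh.write(f">{label}\n{aln.sequence(label)}\n")


def read_annotation(path) -> dict[str, set[str]]:
    """Read a gene<TAB>category[;category...] annotation table."""
    annotation: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        gene, cats = fields
        annotation.setdefault(gene, set()).update(
            c for c in cats.split(";") if c
        )
    return annotation


def write_annotation(annotation: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation):
            fh.write(f"{gene}\t{';'.join(sorted(annotation[gene]))}\n")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as newick: 6-dp branch lengths, lexicographic children."""
    Path(path).write_text(tree_to_newick(tree, precision=6) + "\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of the count-analysis pipeline.

    counts: path to the raw count TSV. annotation: optional gene-category
    TSV enabling the enrichment stage. stress_library: optional label of a
    whole-plant stress library (excluded from nothing, but used for the
    stress-responsive call). normalization: 'quantile' or 'total'.
    """

    counts: str
    out_dir: str
    annotation: str | None = None
    stress_library: str | None = None
    normalization: str = "quantile"
    r_min: float = 8.0
    fold_min: float = 2.0
    alpha_nonsignificant: float = 0.05
    enrichment_cutoff: float = 0.01
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write one TSV per stage plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = PegThresholds(
        r_min=config.r_min,
        fold_min=config.fold_min,
        alpha_nonsignificant=config.alpha_nonsignificant,
    )
    stage_rows: dict[str, int] = {}
    outputs: list[Path] = []

    def emit(name: str, frame: pd.DataFrame, index_label="gene") -> None:
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", float_format="%.6g", index_label=index_label)
        stage_rows[name] = len(frame)
        outputs.append(path)

    def stage(name):
        start = time.perf_counter()
        log.info("stage %s ...", name)
        return lambda: log.info(
            "stage %s done in %.2fs", name, time.perf_counter() - start
        )

    done = stage("read")
    matrix = read_count_table(config.counts)
    done()

    done = stage("normalize")
    if config.normalization == "quantile":
        normalized = quantile_normalize(matrix)
    elif config.normalization == "total":
        normalized = library_total_scale(matrix, float(np.mean(matrix.sum(axis=0))))
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")
    emit("normalized", normalized)
    done()

    done = stage("r_test")
    rres = r_test_matrix(normalized)
    emit("r_test", rres)
    done()

    done = stage("peg")
    organ_cols = [
        c for c in normalized.columns if c != config.stress_library
    ]
    organ = normalized[organ_cols]
    pegs = call_pegs(organ, thresholds)
    emit("pegs", pegs)
    done()

    done = stage("ubiquitous")
    ubiquitous = call_ubiquitous(organ, thresholds)
    emit("ubiquitous", pd.DataFrame(index=pd.Index(ubiquitous, name="gene")))
    done()

    if config.stress_library is not None:
        done = stage("stress")
        stress = call_stress_responsive(normalized, config.stress_library, thresholds)
        emit("stress", stress)
        done()

    done = stage("entropy")
    libs, genes = entropy_profile(normalized)
    emit("entropy_libraries", libs, index_label="library")
    emit("entropy_genes", genes)
    done()

    if config.annotation is not None:
        done = stage("enrichment")
        annotation = read_annotation(config.annotation)
        universe = set(annotation)
        tables = []
        for lib in sorted(pegs["library"].unique()):
            query = [
                g for g in pegs.index[pegs["library"] == lib] if g in universe
            ]
            if not query:
                continue
            table = category_overrepresentation(
                annotation, query, universe, cutoff=config.enrichment_cutoff
            )
            table.insert(0, "library", lib)
            tables.append(table)
        enrichment = (
            pd.concat(tables)
            if tables
            else pd.DataFrame(
                columns=["library", "N", "K", "n", "k", "p_raw", "p_bonferroni", "significant"]
            )
        )
        emit("enrichment", enrichment, index_label="category")
        done()

    manifest = {
        "package": "trexp",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "thresholds": asdict(thresholds)
        if hasattr(thresholds, "__dataclass_fields__")
        else vars(thresholds),
        "stage_rows": stage_rows,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
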