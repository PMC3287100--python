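"""Shared fixtures: random count tables, on-the-fly GenBank records, and
an independent brute-force ENC oracle used to cross-check the estimator."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from codonuse.codon_stats import CodonCounts


def brute_force_enc(counts: dict[str, int]) -> float | None:
    """Independent ENC evaluation straight from the homozygosity formulas.

    Re-derives the synonymous families from Biopython's codon table and
    applies F = (n * sum p_j^2 - 1) / (n - 1) per family, class means, the
    (F2+F4)/2 imputation for a missing 3-fold mean, and the
    2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 sum capped at 61.  Deliberately written
    with plain loops, independent of the package's vectorized path.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    f_per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in families.items():
        k = len(codons)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_per_class[k].append(f)
    means = {k: sum(v) / len(v) for k, v in f_per_class.items() if v}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if any(k not in means for k in (2, 3, 4, 6)):
        return None
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(max(value, 20.0), 61.0)


def random_count_table(rng: np.random.Generator,
                       max_count: int = 40) -> CodonCounts:
    """A random 64-cell count table (sense codons only)."""
    from codonuse.genetic_code import SENSE_CODONS

    counts = {c: int(rng.integers(0, max_count + 1)) for c in SENSE_CODONS}
    if sum(counts.values()) == 0:
        counts["TTT"] = 1
    return CodonCounts(counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from {id: sequence} pairs."""

    def _write(records: dict[str, str], name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in records.items())
        )
        return path

    return _write


@pytest.fixture
def genbank_file(tmp_path):
    """Factory writing a single-record GenBank file with CDS features.

    ``cds_locations`` is a list of location specs; each spec is either a
    (start, end) tuple or a list of such tuples (compound join), with an
    optional trailing strand (-1 for complement).
    """

    def _write(genome: str, cds_locations, name: str = "input.gb",
               record_id: str = "SYN0001"):
        features = []
        for i, loc in enumerate(cds_locations):
            strand = 1
            if isinstance(loc, tuple) and len(loc) == 3:
                start, end, strand = loc
                location = SimpleLocation(start, end, strand=strand)
            elif isinstance(loc, tuple):
                location = SimpleLocation(loc[0], loc[1], strand=1)
            else:  # list of parts -> compound join
                parts = [SimpleLocation(s, e, strand=1) for s, e in loc]
                location = CompoundLocation(parts)
            features.append(
                SeqFeature(location, type="CDS",
                           qualifiers={"gene": [f"g{i + 1}"]})
            )
        rec = SeqRecord(Seq(genome), id=record_id, name=record_id,
                        description="synthetic test record",
                        annotations={"molecule_type": "DNA"},
                        features=features)
        path = tmp_path / name
        SeqIO.write([rec], str(path), "genbank")
        return path

    return _write
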