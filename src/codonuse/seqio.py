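"""Reading, validating and normalizing protein-coding sequences.

Input is multi-record FASTA or GenBank flat files with annotated CDS
features.  Every record is normalized (uppercase, U -> T) and validated
against a :class:`ValidationPolicy` before anything downstream sees it.
For GenBank input the default convention is to concatenate every annotated
CDS of a record into one coding sequence, each CDS read in its own frame —
in genomes with overlapping reading frames (hepadnaviruses being the
motivating case) the same genomic nucleotide then contributes once per gene
that spans it, which is what frame-dependent codon statistics require.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .genetic_code import STOP_CODONS, is_ambiguous


class InputError(ValueError):
    """Unusable input file (missing, empty, or unparseable)."""


class SequenceValidationError(ValueError):
    """A record violated the active validation policy."""


@dataclasses.dataclass(frozen=True)
class ValidationPolicy:
    """What to do with records that are not clean in-frame CDS.

    on_bad_length
        ``error`` rejects sequences whose length is not a multiple of 3;
        ``truncate-trailing`` silently drops the 1-2 trailing nucleotides.
    on_internal_stop
        ``error`` rejects records with a stop codon before the final codon;
        ``warn-and-keep`` admits them with a warning flag on the record.
    on_ambiguous
        ``skip-codon`` flags codons containing non-ACGT symbols so that all
        downstream counting ignores them; ``error`` rejects the record.
    """

    on_bad_length: Literal["error", "truncate-trailing"] = "error"
    on_internal_stop: Literal["error", "warn-and-keep"] = "warn-and-keep"
    on_ambiguous: Literal["skip-codon", "error"] = "skip-codon"

    def __post_init__(self) -> None:
        if self.on_bad_length not in ("error", "truncate-trailing"):
            raise ValueError(f"bad on_bad_length: {self.on_bad_length!r}")
        if self.on_internal_stop not in ("error", "warn-and-keep"):
            raise ValueError(f"bad on_internal_stop: {self.on_internal_stop!r}")
        if self.on_ambiguous not in ("skip-codon", "error"):
            raise ValueError(f"bad on_ambiguous: {self.on_ambiguous!r}")


@dataclasses.dataclass
class CodingSequence:
    """One validated protein-coding nucleotide sequence.

    ``sequence`` is an uppercase DNA string whose length is a multiple of 3.
    ``codons`` is its in-frame triplet decomposition; codons containing a
    non-ACGT symbol are listed in ``ambiguous_indices`` and excluded from all
    downstream counts.  ``warnings`` records policy-admitted anomalies
    (internal stop codons).  ``meta`` carries free-form strain labels
    (country, genotype, subtype, simulation group) used only for reporting.
    """

    id: str
    sequence: str
    meta: dict[str, str] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0 or len(self.sequence) % 3 != 0:
            raise SequenceValidationError(
                f"{self.id}: sequence length {len(self.sequence)} is not a "
                "positive multiple of 3"
            )

    @property
    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def ambiguous_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.codons) if is_ambiguous(c)]

    def counted_codons(self) -> list[str]:
        """Codons visible to downstream counting: the unambiguous ones.

        Stop codons are included here (they are part of the record) but all
        composition/RSCU/ENC statistics ignore them, as stops carry no
        synonymous-usage information.
        """
        return [c for c in self.codons if not is_ambiguous(c)]


def _validate(
    rec_id: str,
    raw: str,
    policy: ValidationPolicy,
    meta: dict[str, str] | None = None,
) -> CodingSequence:
    seq = raw.upper().replace("U", "T")
    if len(seq) == 0:
        raise SequenceValidationError(f"{rec_id}: empty sequence")
    if len(seq) % 3 != 0:
        if policy.on_bad_length == "error":
            raise SequenceValidationError(
                f"{rec_id}: length {len(seq)} not divisible by 3 "
                f"(offending tail starts at position {len(seq) - len(seq) % 3})"
            )
        seq = seq[: len(seq) - len(seq) % 3]
        if len(seq) == 0:
            raise SequenceValidationError(
                f"{rec_id}: no complete codon after truncation"
            )

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    warnings: list[str] = []
    for i, codon in enumerate(codons):
        if is_ambiguous(codon):
            if policy.on_ambiguous == "error":
                raise SequenceValidationError(
                    f"{rec_id}: ambiguous codon {codon!r} at codon {i + 1} "
                    f"(nt position {3 * i + 1})"
                )
            continue  # skip-codon: flagged via ambiguous_indices
        if codon in STOP_CODONS and i < len(codons) - 1:
            if policy.on_internal_stop == "error":
                raise SequenceValidationError(
                    f"{rec_id}: internal stop codon {codon} at codon {i + 1} "
                    f"(nt position {3 * i + 1})"
                )
            warnings.append(f"internal stop codon {codon} at codon {i + 1}")

    return CodingSequence(
        id=rec_id, sequence=seq, meta=dict(meta or {}), warnings=warnings
    )


def read_fasta(
    path: str | Path, policy: ValidationPolicy | None = None
) -> list[CodingSequence]:
    """Read a (multi-record) FASTA file into validated coding sequences.

    Record order is preserved; RNA (U) is normalized to DNA (T).
    Raises :class:`InputError` for empty files and
    :class:`SequenceValidationError` for records failing the policy.
    """
    policy = policy or ValidationPolicy()
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return [_validate(r.id, str(r.seq), policy) for r in records]


def read_genbank_cds(
    path: str | Path,
    policy: ValidationPolicy | None = None,
    join_mode: Literal["concatenate-all-cds", "per-cds"] = "concatenate-all-cds",
) -> list[CodingSequence]:
    """Extract CDS features from a GenBank flat file.

    ``concatenate-all-cds`` yields one coding sequence per GenBank record,
    formed by concatenating every annotated CDS (compound join/complement
    locations honored; overlapping genomic regions contribute once per CDS
    spanning them).  ``per-cds`` yields one coding sequence per CDS feature.
    """
    if join_mode not in ("concatenate-all-cds", "per-cds"):
        raise ValueError(f"bad join_mode: {join_mode!r}")
    policy = policy or ValidationPolicy()
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise InputError(f"{path}: no GenBank records found")

    out: list[CodingSequence] = []
    for rec in records:
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        if not cds_feats:
            raise SequenceValidationError(
                f"{rec.id}: record has no CDS features"
            )
        parts = []
        for i, feat in enumerate(cds_feats):
            try:
                sub = str(feat.extract(rec.seq))
            except Exception as exc:  # malformed location grammar
                raise SequenceValidationError(
                    f"{rec.id}: cannot extract CDS feature {i + 1} "
                    f"({feat.location}): {exc}"
                ) from exc
            label = feat.qualifiers.get("gene", feat.qualifiers.get(
                "protein_id", [f"cds{i + 1}"]))[0]
            parts.append((label, sub))
        if join_mode == "per-cds":
            for label, sub in parts:
                out.append(
                    _validate(f"{rec.id}|{label}", sub, policy,
                              meta={"record": rec.id, "cds": label})
                )
        else:
            joined = "".join(sub for _, sub in parts)
            out.append(
                _validate(rec.id, joined, policy,
                          meta={"n_cds": str(len(parts))})
            )
    return out


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences as unwrapped multi-FASTA (DNA spelling)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.sequence}\n")
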