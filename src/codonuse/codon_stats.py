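"""Core codon-usage statistics on a single codon-count table.

The quantities here are the classical descriptors of synonymous codon usage
bias:

* nucleotide **composition**, overall and at the synonymous third position
  (the T%/C%/A%/G% and T3%/C3%/A3%/G3% columns of a composition table),
  plus the GC12 / GC3 partition;
* **RSCU**, the relative synonymous codon usage: for amino acid *i* with
  *n_i* synonymous codons and codon counts *x_ij*,
  ``RSCU_ij = x_ij * n_i / X_i`` where ``X_i = sum_j x_ij``.  A value of 1
  means the codon is used exactly as often as expected under equal usage
  within its family; family values sum to the family's degeneracy;
* **ENC**, Wright's effective number of codons, built from mean
  within-family homozygosities ``F = (n * sum_j p_j^2 - 1) / (n - 1)``
  averaged per degeneracy class: ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``,
  ranging from 20 (one codon per amino acid) to 61 (all synonymous codons
  used equally);
* the **expected-ENC curve** ``ENC(s) = 2 + s + 29 / (s^2 + (1-s)^2)``,
  the ENC predicted when third-position composition (GC3 = s) alone drives
  codon choice.  Strains plotting below this curve show bias beyond what
  mutation pressure explains.

All functions take a :class:`CodonCounts` table; stop codons present in the
table are ignored by every statistic (they carry no synonymous-usage
information), and the synonymous third-position pools further exclude ATG
and TGG.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, overload

import numpy as np

from .genetic_code import (
    AA_TO_CODONS,
    ALL_CODONS,
    BASES,
    DEGENERACY,
    DEGENERACY_CLASSES,
    MULTI_CODON_AAS,
    SENSE_CODONS,
    SYNONYMOUS_CODONS,
)
from .seqio import CodingSequence

__all__ = [
    "CodonCounts",
    "CompositionProfile",
    "RSCUVector",
    "ENCResult",
    "count_codons",
    "composition",
    "gc_partition",
    "rscu",
    "classify_representation",
    "enc",
    "expected_enc",
]

#: representation-class thresholds (strict inequalities)
OVER_REPRESENTED_RSCU = 1.6
UNDER_REPRESENTED_RSCU = 0.6


@dataclasses.dataclass
class CodonCounts:
    """The 64-cell codon count table for one sequence or a pooled set."""

    counts: dict[str, int]
    source_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}: {n}")
            full[codon] = int(n)
        self.counts = full

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def n_sense(self) -> int:
        return sum(self.counts[c] for c in SENSE_CODONS)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = {
            c: self.counts[c] + other.counts[c] for c in ALL_CODONS
        }
        return CodonCounts(merged, self.source_ids + other.source_ids)


@dataclasses.dataclass(frozen=True)
class CompositionProfile:
    """Overall and synonymous-third-position nucleotide percentages.

    ``overall`` covers all three positions of every counted sense codon;
    ``third_syn`` covers third positions of synonymous sense codons only
    (ATG, TGG and stops excluded) and is ``None`` when no such codon was
    observed.  ``gc12`` pools positions 1 and 2; ``gc3`` is the G+C percent
    of the ``third_syn`` pool.  All values are percentages in [0, 100].
    """

    overall: dict[str, float]
    third_syn: dict[str, float] | None
    gc12: float
    gc3: float | None


@dataclasses.dataclass(frozen=True)
class RSCUVector:
    """RSCU values for the 59 synonymous sense codons of one count table.

    ``values`` always has 59 keys; codons whose amino-acid family is absent
    from the table are NaN there and listed in ``undefined``.
    """

    values: dict[str, float]
    undefined: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.values) != set(SYNONYMOUS_CODONS):
            raise ValueError("RSCU vector must index exactly the 59 "
                             "synonymous sense codons")

    def defined_items(self) -> list[tuple[str, float]]:
        return [(c, v) for c, v in self.values.items()
                if c not in self.undefined]


@dataclasses.dataclass(frozen=True)
class ENCResult:
    """ENC value plus per-degeneracy-class homozygosity diagnostics.

    ``enc`` is ``None`` when a required class mean is unavailable;
    ``f_bar`` maps degeneracy class k in {2, 3, 4, 6} to the mean
    homozygosity F̄k actually used (including an imputed F̄3);
    ``families_used`` counts contributing families per class and
    ``imputed_classes`` lists classes whose mean was imputed.
    """

    enc: float | None
    f_bar: dict[int, float]
    families_used: dict[int, int]
    imputed_classes: tuple[int, ...] = ()


@overload
def count_codons(seqs: CodingSequence, pool: bool = ...) -> CodonCounts: ...
@overload
def count_codons(seqs: Iterable[CodingSequence], pool: bool = ...
                 ) -> CodonCounts | list[CodonCounts]: ...


def count_codons(seqs, pool=False):
    """Count codons for one or more validated coding sequences.

    With ``pool=False`` (default) returns one table per sequence (or a bare
    table for a single sequence); with ``pool=True`` a single table summed
    across all inputs.  Ambiguous-flagged codons are never counted; stop
    codons are counted in the table but ignored by every statistic.
    """
    if isinstance(seqs, CodingSequence):
        seqs = [seqs]
        single = True
    else:
        seqs = list(seqs)
        single = False
    if not seqs:
        raise ValueError("count_codons: empty input")

    tables = []
    for s in seqs:
        counts: dict[str, int] = {}
        for codon in s.counted_codons():
            counts[codon] = counts.get(codon, 0) + 1
        tables.append(CodonCounts(counts, source_ids=[s.id]))
    if pool:
        total = tables[0]
        for t in tables[1:]:
            total = total + t
        return total
    return tables[0] if single else tables


def _position_base_counts(counts: CodonCounts, position: int,
                          codons: Iterable[str]) -> dict[str, int]:
    out = {b: 0 for b in BASES}
    for codon in codons:
        out[codon[position]] += counts.counts[codon]
    return out


def composition(counts: CodonCounts) -> CompositionProfile:
    """Nucleotide composition profile of a codon count table.

    Overall percentages are over all 3 positions of counted sense codons;
    the third-position pool is restricted to synonymous sense codons.
    """
    if counts.n_sense < 1:
        raise ValueError("composition: no counted sense codons")

    overall = {b: 0 for b in BASES}
    for pos in range(3):
        for b, n in _position_base_counts(counts, pos, SENSE_CODONS).items():
            overall[b] += n
    tot = sum(overall.values())
    overall_pct = {b: 100.0 * n / tot for b, n in overall.items()}

    pos12 = {b: 0 for b in BASES}
    for pos in (0, 1):
        for b, n in _position_base_counts(counts, pos, SENSE_CODONS).items():
            pos12[b] += n
    gc12 = 100.0 * (pos12["G"] + pos12["C"]) / sum(pos12.values())

    third = _position_base_counts(counts, 2, SYNONYMOUS_CODONS)
    n3 = sum(third.values())
    if n3 == 0:
        third_pct, gc3 = None, None
    else:
        third_pct = {b: 100.0 * n / n3 for b, n in third.items()}
        gc3 = third_pct["G"] + third_pct["C"]

    return CompositionProfile(overall=overall_pct, third_syn=third_pct,
                              gc12=gc12, gc3=gc3)


def gc_partition(counts: CodonCounts) -> tuple[float, float | None]:
    """(GC12, GC3) percentages; GC3 is None without synonymous codons."""
    prof = composition(counts)
    return prof.gc12, prof.gc3


def rscu(counts: CodonCounts) -> RSCUVector:
    """Relative synonymous codon usage of a count table.

    ``RSCU_ij = x_ij * n_i / X_i`` per codon j of amino acid i.  Families
    with zero occurrences yield NaN values listed in ``undefined`` — an
    absent family has no usage pattern, which is distinct from RSCU 0.
    """
    if counts.n_sense < 1:
        raise ValueError("rscu: no counted sense codons")
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for aa in MULTI_CODON_AAS:
        family = AA_TO_CODONS[aa]
        total = sum(counts.counts[c] for c in family)
        if total == 0:
            for c in family:
                values[c] = math.nan
                undefined.add(c)
        else:
            deg = DEGENERACY[aa]
            for c in family:
                values[c] = counts.counts[c] * deg / total
    return RSCUVector(values=values, undefined=frozenset(undefined))


def classify_representation(v: RSCUVector) -> dict[str, str]:
    """Classify each codon as over/under/normal per the RSCU thresholds.

    Strictly greater than 1.6 is over-represented, strictly less than 0.6
    under-represented; boundary values are normal; codons of absent
    families are 'undefined'.
    """
    out = {}
    for codon, value in v.values.items():
        if codon in v.undefined:
            out[codon] = "undefined"
        elif value > OVER_REPRESENTED_RSCU:
            out[codon] = "over"
        elif value < UNDER_REPRESENTED_RSCU:
            out[codon] = "under"
        else:
            out[codon] = "normal"
    return out


def _family_homozygosity(counts: Mapping[str, int],
                         family: Iterable[str]) -> float | None:
    """Wright's F for one family; None when n < 2 or F <= 0 (unusable)."""
    x = np.array([counts[c] for c in family], dtype=float)
    n = x.sum()
    if n < 2:
        return None
    p = x / n
    f = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
    if f <= 0:
        return None
    return f


def enc(counts: CodonCounts) -> ENCResult:
    """Wright's effective number of codons for a count table.

    Families contribute F = (n·Σp² − 1)/(n − 1) when usable (n ≥ 2 and
    F > 0); class means F̄k are averaged over contributing families and
    ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6, capped at 61.  A missing F̄3
    (isoleucine sparse or unusable) is imputed as (F̄2 + F̄4)/2; if F̄2,
    F̄4 or F̄6 is missing the ENC is reported missing with diagnostics
    rather than raising.
    """
    if counts.n_codons < 1:
        raise ValueError("enc: empty count table")

    f_by_class: dict[int, list[float]] = {k: [] for k in (2, 3, 4, 6)}
    for k, aas in DEGENERACY_CLASSES.items():
        for aa in aas:
            f = _family_homozygosity(counts.counts, AA_TO_CODONS[aa])
            if f is not None:
                f_by_class[k].append(f)

    f_bar = {k: (sum(v) / len(v)) for k, v in f_by_class.items() if v}
    families_used = {k: len(v) for k, v in f_by_class.items()}
    imputed: tuple[int, ...] = ()

    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
        imputed = (3,)

    if not all(k in f_bar for k in (2, 3, 4, 6)):
        return ENCResult(enc=None, f_bar=f_bar,
                         families_used=families_used,
                         imputed_classes=imputed)

    value = 2.0 + 9.0 / f_bar[2] + 1.0 / f_bar[3] + 5.0 / f_bar[4] \
        + 3.0 / f_bar[6]
    value = min(value, 61.0)
    value = max(value, 20.0)
    return ENCResult(enc=value, f_bar=f_bar, families_used=families_used,
                     imputed_classes=imputed)


def expected_enc(gc3: float) -> float:
    """ENC expected under third-position compositional constraint alone.

    ``ENC(s) = 2 + s + 29 / (s^2 + (1-s)^2)`` with s = GC3 as a fraction
    in [0, 1].  Observed points below this curve indicate forces beyond
    mutation pressure (e.g. translational selection).
    """
    s = float(gc3)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"expected_enc: GC3 fraction {s} outside [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))
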