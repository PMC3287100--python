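"""Virus-vs-host codon usage concordance.

A viral RSCU vector is compared codon by codon against a bundled host
reference.  A codon is *coincident* when virus and host fall on the same
side of the neutral value 1 (both preferred or both avoided), and
*antagonistic* when the directions differ.  Codons the virus uses above
neutral while the host under-represents them (host RSCU < 0.6) are singled
out: such usage runs directly against host tRNA-matched preference and is
the signature of the antagonistic portion of a viral codon usage pattern.

The packaged ``human-Table2`` reference is a frozen published human RSCU
column (59 synonymous sense codons); a pooled ``hbv-Table2`` viral column
from the same source is bundled alongside for worked examples.  Freezing
the printed values keeps results download-free and stable.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources

import pandas as pd

from .codon_stats import RSCUVector, UNDER_REPRESENTED_RSCU
from .genetic_code import AA_TO_CODONS, CODON_TO_AA, DEGENERACY, \
    MULTI_CODON_AAS, SYNONYMOUS_CODONS

__all__ = [
    "HostReferenceTable",
    "ComparisonReport",
    "available_references",
    "load_host_reference",
    "compare_rscu",
    "similarity_score",
]

_REFERENCE_COLUMNS = {"human-Table2": "human_rscu"}


@dataclasses.dataclass(frozen=True)
class HostReferenceTable:
    """A frozen 59-codon RSCU reference for one organism."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(SYNONYMOUS_CODONS):
            raise ValueError("reference must cover the 59 synonymous "
                             "sense codons")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("reference RSCU values must be positive")
        for aa in MULTI_CODON_AAS:
            fam_sum = sum(self.values[c] for c in AA_TO_CODONS[aa])
            if abs(fam_sum - DEGENERACY[aa]) > 0.15:
                raise ValueError(
                    f"family {aa} sums to {fam_sum:.2f}, outside the "
                    f"2-decimal rounding tolerance of {DEGENERACY[aa]}"
                )


@dataclasses.dataclass(frozen=True)
class ComparisonReport:
    """Per-codon and per-family concordance between virus and host.

    ``per_codon`` maps each comparable codon to
    (classification, virus RSCU, host RSCU); ``per_family`` maps each
    amino acid to (n coincident, n antagonistic, preferred-codon match);
    ``highly_used_against_host`` lists codons with virus RSCU > 1 while
    the host under-represents them (host RSCU < 0.6).
    """

    per_codon: dict[str, tuple[str, float, float]]
    per_family: dict[str, tuple[int, int, bool]]
    highly_used_against_host: tuple[str, ...]


def available_references() -> tuple[str, ...]:
    return tuple(sorted(_REFERENCE_COLUMNS))


def _reference_frame() -> pd.DataFrame:
    with resources.files("codonuse.data").joinpath(
            "rscu_reference_table2.csv").open() as fh:
        return pd.read_csv(fh)


def load_host_reference(name: str = "human-Table2") -> HostReferenceTable:
    """Load a bundled RSCU reference by name.

    Unknown names raise a KeyError listing the available references.
    """
    if name not in _REFERENCE_COLUMNS:
        raise KeyError(
            f"unknown reference {name!r}; available: "
            f"{', '.join(available_references())}"
        )
    df = _reference_frame()
    col = _REFERENCE_COLUMNS[name]
    values = dict(zip(df["codon"], df[col].astype(float)))
    return HostReferenceTable(name=name, values=values)


def bundled_virus_rscu() -> RSCUVector:
    """The pooled viral RSCU column bundled next to the host reference.

    Returned as a plain RSCU vector, not a validated reference table: the
    printed source values do not satisfy the family-sum identity exactly
    (rounding and typesetting artifacts), so they are suitable for worked
    comparison examples but not as a reference standard.
    """
    df = _reference_frame()
    return RSCUVector(values=dict(zip(df["codon"],
                                      df["hbv_rscu"].astype(float))),
                      undefined=frozenset())


def _side(value: float) -> int:
    """-1 below neutral usage, +1 at or above (ties side with >= 1)."""
    return 1 if value >= 1.0 else -1


def compare_rscu(virus: RSCUVector | HostReferenceTable,
                 host: HostReferenceTable) -> ComparisonReport:
    """Classify per-codon concordance of viral vs host codon usage.

    A codon is coincident iff both RSCU values sit on the same side of 1
    (values exactly 1.0 count as the upper side on either argument, so a
    neutral codon is coincident with any preferred one).  Codons whose
    family is absent from the virus are excluded.  The per-family summary
    additionally reports whether the most-used (argmax RSCU) codon is the
    same in virus and host.
    """
    if isinstance(virus, HostReferenceTable):
        v_values = dict(virus.values)
        v_undefined: frozenset[str] = frozenset()
    else:
        v_values = virus.values
        v_undefined = virus.undefined

    per_codon: dict[str, tuple[str, float, float]] = {}
    against: list[str] = []
    for codon in SYNONYMOUS_CODONS:
        if codon in v_undefined:
            continue
        v = v_values[codon]
        h = host.values[codon]
        cls = "coincident" if _side(v) == _side(h) else "antagonistic"
        per_codon[codon] = (cls, v, h)
        if v > 1.0 and h < UNDER_REPRESENTED_RSCU:
            against.append(codon)

    per_family: dict[str, tuple[int, int, bool]] = {}
    for aa in MULTI_CODON_AAS:
        family = [c for c in AA_TO_CODONS[aa] if c in per_codon]
        if not family:
            continue
        n_co = sum(1 for c in family if per_codon[c][0] == "coincident")
        n_an = len(family) - n_co
        v_pref = max(family, key=lambda c: per_codon[c][1])
        h_pref = max(AA_TO_CODONS[aa], key=lambda c: host.values[c])
        per_family[aa] = (n_co, n_an, v_pref == h_pref)

    return ComparisonReport(per_codon=per_codon, per_family=per_family,
                            highly_used_against_host=tuple(against))


def similarity_score(virus: RSCUVector | HostReferenceTable,
                     host: HostReferenceTable) -> float:
    """Pearson correlation between virus and host RSCU vectors.

    Quantifies overall resemblance of usage patterns on a [-1, 1] scale;
    NaN when fewer than 2 codons are comparable or either vector is
    constant.  Undefined viral codons are excluded pairwise.
    """
    from .multivariate import pearson

    if isinstance(virus, HostReferenceTable):
        v_values = dict(virus.values)
        v_undefined: frozenset[str] = frozenset()
    else:
        v_values = virus.values
        v_undefined = virus.undefined

    codons = [c for c in SYNONYMOUS_CODONS if c not in v_undefined]
    if len(codons) < 3:
        return math.nan
    x = [v_values[c] for c in codons]
    y = [host.values[c] for c in codons]
    r, _, _ = pearson(x, y)
    return r


def comparison_frame(report: ComparisonReport) -> pd.DataFrame:
    """Tabulate a comparison report (codon, amino acid, values, class)."""
    rows = [
        {
            "codon": codon,
            "amino_acid": CODON_TO_AA[codon],
            "virus_rscu": v,
            "host_rscu": h,
            "classification": cls,
        }
        for codon, (cls, v, h) in report.per_codon.items()
    ]
    return pd.DataFrame(rows)
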