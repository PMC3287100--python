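"""Synthetic coding-sequence cohorts with controlled codon-usage forces.

The generator separates the two forces the analysis pipeline is built to
disentangle:

* a **mutation model** — independent nucleotide probabilities at each of
  the three codon positions, emulating directional mutation pressure from
  genome composition;
* a **selection model** — target RSCU preferences within each synonymous
  family, emulating translational selection for particular codons.

An amino-acid sequence is drawn first (i.i.d. from a profile), then the
codon for each residue is drawn *within its family* from the mixture
``(1-w) * P_mut(codon | family) + w * P_sel(codon | family)``.  Because the
amino-acid composition and the synonymous preference are controlled
independently, RSCU's invariance to amino-acid composition is directly
testable, and ``w`` sweeps continuously from a pure mutation-pressure null
(points on the expected ENC-GC3 curve) to pure selection (points below
it).  Stop codons are never generated internally; a single terminal stop
drawn from the mutation model closes each sequence.

Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    BASES,
    DEGENERACY,
    MULTI_CODON_AAS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
)
from .seqio import CodingSequence, write_fasta

__all__ = [
    "MutationModel",
    "SelectionModel",
    "CohortSpec",
    "simulate_cds",
    "simulate_groups",
    "write_cohort",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclasses.dataclass(frozen=True)
class MutationModel:
    """Per-codon-position nucleotide probabilities (3 x 4, ACGT order)."""

    pos_probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pos_probs, dtype=float)
        if p.shape != (3, 4):
            raise ValueError("pos_probs must be 3 vectors over {A,C,G,T}")
        if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each position vector must be a probability "
                             "distribution")
        object.__setattr__(self, "pos_probs", p)

    @classmethod
    def uniform(cls) -> "MutationModel":
        return cls(np.full((3, 4), 0.25))

    @classmethod
    def with_gc3(cls, gc3: float,
                 pos12: Sequence[float] | None = None) -> "MutationModel":
        """Symmetric third-position composition at a target GC3 fraction.

        Third-position probabilities are G = C = gc3/2 and
        A = T = (1-gc3)/2 — the symmetric composition the expected-ENC
        curve is parameterized by.  Positions 1-2 default to uniform.
        """
        if not 0.0 <= gc3 <= 1.0:
            raise ValueError("gc3 must be a fraction in [0, 1]")
        p12 = np.full(4, 0.25) if pos12 is None else np.asarray(pos12, float)
        p3 = np.array([(1 - gc3) / 2, gc3 / 2, gc3 / 2, (1 - gc3) / 2])
        return cls(np.vstack([p12, p12, p3]))

    def codon_prob(self, codon: str) -> float:
        return float(np.prod([
            self.pos_probs[i, _BASE_INDEX[b]] for i, b in enumerate(codon)
        ]))


@dataclasses.dataclass(frozen=True)
class SelectionModel:
    """Target within-family codon preferences as an RSCU-scale table.

    ``target_rscu`` maps each of the 59 synonymous sense codons to a
    non-negative preference; per-family values must sum to the family
    degeneracy (the RSCU normalization), so dividing by the degeneracy
    gives the within-family codon probabilities selection aims at.
    """

    target_rscu: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.target_rscu) != set(SYNONYMOUS_CODONS):
            raise ValueError("target_rscu must cover the 59 synonymous "
                             "sense codons")
        if any(v < 0 for v in self.target_rscu.values()):
            raise ValueError("target preferences must be non-negative")
        for aa in MULTI_CODON_AAS:
            s = sum(self.target_rscu[c] for c in AA_TO_CODONS[aa])
            if abs(s - DEGENERACY[aa]) > 1e-9:
                raise ValueError(
                    f"family {aa}: target values sum to {s}, expected "
                    f"{DEGENERACY[aa]}"
                )

    @classmethod
    def uniform(cls) -> "SelectionModel":
        return cls({c: 1.0 for c in SYNONYMOUS_CODONS})

    @classmethod
    def concentrated(cls, preferred: Mapping[str, str],
                     strength: float = 1.0) -> "SelectionModel":
        """Concentrate mass on one preferred codon per family.

        ``preferred`` maps each multi-codon amino acid to its favored
        codon; that codon receives a fraction ``strength`` of the family
        mass, the rest shared equally by the remaining codons.
        ``strength=1`` is maximal bias (one codon per amino acid).
        """
        if not 0.0 < strength <= 1.0:
            raise ValueError("strength must be in (0, 1]")
        values: dict[str, float] = {}
        for aa in MULTI_CODON_AAS:
            family = AA_TO_CODONS[aa]
            pref = preferred.get(aa)
            if pref not in family:
                raise ValueError(f"no preferred codon given for {aa}")
            deg = DEGENERACY[aa]
            rest = deg * (1.0 - strength) / (deg - 1)
            for c in family:
                values[c] = deg * strength if c == pref else rest
        return cls(values)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Size, mixture weight, amino-acid profile and seed of one cohort.

    ``w`` interpolates codon choice between the mutation model (0) and
    the selection model (1).  ``amino_acid_profile`` maps one-letter
    amino acids to probabilities (default: uniform over the 20).
    """

    n_strains: int
    n_codons: int
    w: float = 0.0
    amino_acid_profile: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_codons < 1:
            raise ValueError("n_strains and n_codons must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight w must be in [0, 1]")
        if self.amino_acid_profile is not None:
            p = np.array([self.amino_acid_profile.get(aa, 0.0)
                          for aa in AMINO_ACIDS])
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError("amino_acid_profile must be a probability "
                                 "distribution over amino acids")

    def profile_vector(self) -> np.ndarray:
        if self.amino_acid_profile is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        return np.array([self.amino_acid_profile.get(aa, 0.0)
                         for aa in AMINO_ACIDS])


def _family_mixture(mut: MutationModel, sel: SelectionModel,
                    w: float) -> dict[str, np.ndarray]:
    """Within-family codon probabilities under the (1-w)/w mixture."""
    mix: dict[str, np.ndarray] = {}
    for aa, family in AA_TO_CODONS.items():
        if DEGENERACY[aa] == 1:
            mix[aa] = np.array([1.0])
            continue
        p_mut = np.array([mut.codon_prob(c) for c in family])
        p_sel = np.array([sel.target_rscu[c] for c in family])
        m_sum, s_sum = p_mut.sum(), p_sel.sum()
        p = np.zeros(len(family))
        if m_sum > 0:
            p += (1.0 - w) * p_mut / m_sum
        if s_sum > 0:
            p += w * p_sel / s_sum
        if p.sum() <= 0:
            raise ValueError(
                f"family {aa} has zero probability mass under both models"
            )
        mix[aa] = p / p.sum()
    return mix


def _draw_stop(rng: np.random.Generator, mut: MutationModel) -> str:
    p = np.array([mut.codon_prob(c) for c in STOP_CODONS])
    if p.sum() <= 0:
        p = np.ones(len(STOP_CODONS))
    return STOP_CODONS[int(rng.choice(len(STOP_CODONS), p=p / p.sum()))]


def simulate_cds(spec: CohortSpec, mut: MutationModel | None = None,
                 sel: SelectionModel | None = None,
                 id_prefix: str = "sim",
                 meta: Mapping[str, str] | None = None,
                 ) -> list[CodingSequence]:
    """Generate a cohort of coding sequences under the mixture model.

    Deterministic given ``spec.seed``.  Each sequence has ``spec.n_codons``
    amino-acid-coding codons plus one terminal stop codon.
    """
    mut = mut or MutationModel.uniform()
    sel = sel or SelectionModel.uniform()
    rng = np.random.default_rng(spec.seed)
    mixture = _family_mixture(mut, sel, spec.w)
    profile = spec.profile_vector()
    families = {aa: np.array(AA_TO_CODONS[aa]) for aa in AMINO_ACIDS}

    base_meta = dict(meta or {})
    base_meta.setdefault("w", repr(spec.w))
    base_meta.setdefault("seed", str(spec.seed))

    cohort: list[CodingSequence] = []
    for i in range(spec.n_strains):
        aa_idx = rng.choice(len(AMINO_ACIDS), size=spec.n_codons, p=profile)
        codons = np.empty(spec.n_codons, dtype="<U3")
        for j, aa in enumerate(AMINO_ACIDS):
            mask = aa_idx == j
            k = int(mask.sum())
            if k == 0:
                continue
            fam = families[aa]
            if len(fam) == 1:
                codons[mask] = fam[0]
            else:
                draw = rng.choice(len(fam), size=k, p=mixture[aa])
                codons[mask] = fam[draw]
        seq = "".join(codons) + _draw_stop(rng, mut)
        cohort.append(CodingSequence(id=f"{id_prefix}{i + 1}",
                                     sequence=seq, meta=dict(base_meta)))
    return cohort


def simulate_groups(
    groups: Sequence[tuple[str, CohortSpec, MutationModel, SelectionModel]],
) -> list[CodingSequence]:
    """Union of cohorts generated under distinct models, labeled by group.

    Each entry is (label, spec, mutation model, selection model); the
    group label lands in each record's ``meta['group']`` for downstream
    coloring and score-separation checks.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out: list[CodingSequence] = []
    for label, spec, mut, sel in groups:
        out.extend(
            simulate_cds(spec, mut, sel, id_prefix=f"{label}_",
                         meta={"group": label})
        )
    return out


def write_cohort(seqs: Sequence[CodingSequence], fasta_path: str | Path,
                 meta_path: str | Path | None = None) -> None:
    """Write a cohort as multi-FASTA plus an optional metadata sidecar TSV."""
    write_fasta(seqs, fasta_path)
    if meta_path is not None:
        keys = sorted({k for s in seqs for k in s.meta})
        with Path(meta_path).open("w") as fh:
            fh.write("id\t" + "\t".join(keys) + "\n")
            for s in seqs:
                fh.write(s.id + "\t"
                         + "\t".join(s.meta.get(k, "") for k in keys) + "\n")
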