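"""Fibril-fragment composition and formal-charge bookkeeping.

Atomic fibril-fragment models are built by stacking copies of a deposited
protofilament layer along the fibril axis: a fragment is ``layers`` layers of
``symmetry`` peptide subunits each (C2 symmetry → two molecules per layer,
C3 → three).  The Aβ40 model derives from the brain-seeded 2M4J structure
(C3, 12 layers → 36 subunits) and the Aβ42 model from 2NAO (C2, 12 layers →
24 subunits).

Formal charges use a fixed-pKa integer rule set: Arg, Lys and the N-terminus
count +1, Asp, Glu and the C-terminus −1, His neutral at physiological pH
(protonated below pH 6 in the simple rules).  Both Aβ peptides then carry −3
per subunit at pH 7.4, giving fragment net charges −108 (Aβ40 36-mer) and
−72 (Aβ42 24-mer).  A Henderson–Hasselbalch fractional mode is available for
non-integer bookkeeping away from the pKa plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PeptideSpec", "FragmentSpec", "StrandAnnotation",
    "AB40_SEQUENCE", "AB42_SEQUENCE", "AB40_PEPTIDE", "AB42_PEPTIDE",
    "AB40_FRAGMENT", "AB42_FRAGMENT",
    "subunit_count", "formal_charge", "fragment_charge", "strand_annotations",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical amyloid-beta sequences (one-letter)
AB40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: side-chain pKa values (simple fixed set) and the charge sign when titrated
_SIDECHAIN_PKA = {
    "D": (3.9, -1), "E": (4.1, -1), "C": (8.3, -1), "Y": (10.1, -1),
    "H": (6.0, +1), "K": (10.5, +1), "R": (12.5, +1),
}
_NTERM_PKA = 9.0
_CTERM_PKA = 3.1


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide identified by its one-letter sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(f"unknown residue letter(s) {sorted(bad)} in {self.id!r}")
        if not self.sequence:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentSpec:
    """A stacked fibril fragment: ``layers`` layers of ``symmetry`` subunits."""

    peptide: PeptideSpec
    layers: int
    symmetry: int
    source_structure: str = ""  # PDB id, metadata only — never parsed

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError(f"layers must be >= 1, got {self.layers}")
        if self.symmetry < 1:
            raise ValueError(f"symmetry must be >= 1, got {self.symmetry}")


@dataclass(frozen=True)
class StrandAnnotation:
    """An intermolecular parallel beta-layer region, 1-based inclusive."""

    label: str
    start: int
    end: int

    def validate_against(self, peptide: PeptideSpec) -> None:
        if not (1 <= self.start <= self.end <= peptide.length):
            raise ValueError(
                f"{self.label}: region {self.start}-{self.end} outside "
                f"1-{peptide.length}")


AB40_PEPTIDE = PeptideSpec("Abeta40", AB40_SEQUENCE)
AB42_PEPTIDE = PeptideSpec("Abeta42", AB42_SEQUENCE)

#: twelve-layer fragment models used for the charge bookkeeping
AB40_FRAGMENT = FragmentSpec(AB40_PEPTIDE, layers=12, symmetry=3,
                             source_structure="2M4J")
AB42_FRAGMENT = FragmentSpec(AB42_PEPTIDE, layers=12, symmetry=2,
                             source_structure="2NAO")

#: printed beta-strand regions of the deposited structures
_STRANDS = {
    "2M4J-like": (StrandAnnotation("beta1", 12, 13),
                  StrandAnnotation("beta2", 18, 19),
                  StrandAnnotation("beta3", 35, 36)),
    "2NAO-like": (StrandAnnotation("beta1", 2, 6),
                  StrandAnnotation("beta2", 15, 18),
                  StrandAnnotation("beta3", 26, 28),
                  StrandAnnotation("beta4", 30, 32),
                  StrandAnnotation("beta5", 39, 42)),
}
_STRAND_PEPTIDE = {"2M4J-like": AB40_PEPTIDE, "2NAO-like": AB42_PEPTIDE}


def subunit_count(fragment: FragmentSpec) -> int:
    """Number of peptide subunits in the fragment (layers × symmetry)."""
    return fragment.layers * fragment.symmetry


def formal_charge(peptide: PeptideSpec, pH: float = 7.4,
                  fractional: bool = False) -> int | float:
    """Formal charge of one peptide subunit at a given pH.

    The default integer rules assign full charges by pKa threshold; with
    ``fractional=True`` each group contributes its Henderson–Hasselbalch
    occupancy instead (sum of ``±1/(1+10^(±(pH−pKa)))`` terms).
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH {pH} outside [0, 14]")
    total = 0.0
    groups = [(_NTERM_PKA, +1), (_CTERM_PKA, -1)]
    groups += [_SIDECHAIN_PKA[aa] for aa in peptide.sequence if aa in _SIDECHAIN_PKA]
    for pka, sign in groups:
        if fractional:
            if sign > 0:  # base: charged when protonated
                total += 1.0 / (1.0 + 10.0 ** (pH - pka))
            else:         # acid: charged when deprotonated
                total -= 1.0 / (1.0 + 10.0 ** (pka - pH))
        else:
            if sign > 0:
                total += 1 if pH < pka else 0
            else:
                total -= 1 if pH > pka else 0
    return total if fractional else int(round(total))


def fragment_charge(fragment: FragmentSpec, pH: float = 7.4,
                    fractional: bool = False) -> int | float:
    """Net formal charge of the whole fragment (per-subunit charge × count)."""
    per_subunit = formal_charge(fragment.peptide, pH, fractional=fractional)
    return per_subunit * subunit_count(fragment)


def strand_annotations(model_id: str) -> tuple[StrandAnnotation, ...]:
    """Beta-strand regions of a known fibril polymorph model.

    ``"2M4J-like"`` (Aβ40, three strands) or ``"2NAO-like"`` (Aβ42, five
    strands); every region is validated against its peptide length.
    """
    if model_id not in _STRANDS:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {sorted(_STRANDS)}")
    strands = _STRANDS[model_id]
    for s in strands:
        s.validate_against(_STRAND_PEPTIDE[model_id])
    return strands
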