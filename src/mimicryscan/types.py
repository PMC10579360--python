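"""Domain types shared by every stage of the mimicry screen.

The pipeline moves four kinds of records around: protein sequences (the
microbial target and human parent antigens), linear epitopes from an immune
epitope catalog, HLA binding predictions consumed as precomputed tables, and
ELISA optical-density measurements. ``ScreenConfig`` collects every tunable
of the screening chain in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "DISEASE_VOCABULARY",
    "ProteinSequence",
    "Epitope",
    "BindingRecord",
    "ELISAMeasurement",
    "ScreenConfig",
    "FormatError",
]

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Accepted residue alphabet: standard residues plus the ambiguity code X.
#: X is accepted but scores 0 against everything during alignment.
ALPHABET = AMINO_ACIDS + "X"

#: Controlled vocabulary of autoimmune-disease abbreviations used throughout:
#: rheumatoid arthritis, ankylosing spondylitis, autoimmune atherosclerosis,
#: psoriatic arthritis, autoimmune thyroiditis, Sjogren's syndrome, primary
#: biliary cholangitis, type 1 diabetes mellitus, multiple sclerosis and
#: autoimmune uveitis. Free-text tags are normalized to upper case but the
#: vocabulary is advisory, not enforced.
DISEASE_VOCABULARY = (
    "RA", "AS", "AIAS", "PA", "AIT", "SS", "PBC", "T1DM", "MS", "AU",
)

#: Assay classes an epitope can carry in the catalog.
ASSAY_CLASSES = ("T cell", "B cell", "HLA-I", "HLA-II")


class FormatError(ValueError):
    """Raised when an input file or record violates its format contract."""


def _check_residues(residues: str, owner: str) -> None:
    bad = sorted({c for c in residues if c not in ALPHABET})
    if bad:
        raise FormatError(
            f"record {owner!r}: illegal residue character(s) {''.join(bad)!r}"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A protein: the microbial target or a human parent antigen.

    Residues are stored upper-cased; any character outside the accepted
    alphabet raises :class:`FormatError` naming the offending record.
    """

    id: str
    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein sequence requires a nonempty id")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        _check_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        """True if the sequence contains the ambiguity code X."""
        return "X" in self.residues


@dataclass(frozen=True)
class Epitope:
    """A linear human peptide with its parent antigen and disease tags."""

    epitope_id: str
    sequence: str
    parent_antigen: str
    antigen_accession: str | None = None
    diseases: frozenset[str] = field(default_factory=frozenset)
    assay_classes: frozenset[str] = field(default_factory=frozenset)
    positive: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise FormatError(f"epitope {self.epitope_id!r}: empty sequence")
        _check_residues(self.sequence, self.epitope_id)
        object.__setattr__(
            self, "diseases", frozenset(d.upper() for d in self.diseases)
        )
        object.__setattr__(self, "assay_classes", frozenset(self.assay_classes))


@dataclass(frozen=True)
class BindingRecord:
    """One predicted peptide-HLA binding affinity (IC50, nM).

    ``hla_class`` is ``"I"`` or ``"II"``; lower IC50 means stronger predicted
    binding, so a record qualifies a peptide as a strong binder when its IC50
    falls below the class threshold.
    """

    peptide: str
    allele: str
    hla_class: str
    ic50_nM: float
    percentile_rank: float | None = None

    def __post_init__(self) -> None:
        if self.hla_class not in ("I", "II"):
            raise FormatError(
                f"binding record for {self.peptide!r}: HLA class must be "
                f"'I' or 'II', got {self.hla_class!r}"
            )
        if not self.ic50_nM > 0:
            raise FormatError(
                f"binding record for {self.peptide!r}: IC50 must be > 0 nM"
            )
        if self.percentile_rank is not None and not (
            0 <= self.percentile_rank <= 100
        ):
            raise FormatError(
                f"binding record for {self.peptide!r}: percentile rank "
                "outside [0, 100]"
            )


@dataclass(frozen=True)
class ELISAMeasurement:
    """Optical densities (405 nm, dimensionless) for one antigen well set."""

    antigen: str
    antibody: str  # "polyclonal" | "monoclonal"
    ods: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.antibody not in ("polyclonal", "monoclonal"):
            raise FormatError(
                f"antigen {self.antigen!r}: antibody must be 'polyclonal' "
                f"or 'monoclonal', got {self.antibody!r}"
            )
        object.__setattr__(self, "ods", tuple(float(x) for x in self.ods))
        if len(self.ods) < 1:
            raise FormatError(f"antigen {self.antigen!r}: no OD replicates")
        if any(x < 0 for x in self.ods):
            raise FormatError(f"antigen {self.antigen!r}: negative OD")

    @property
    def n_replicates(self) -> int:
        return len(self.ods)

    @property
    def mean_od(self) -> float:
        return sum(self.ods) / len(self.ods)

    @property
    def cv_percent(self) -> float | None:
        """Duplicate-well variation, percent; ``None`` for single wells.

        For duplicates this is 100*|od1-od2|/mean; for >= 3 replicates the
        ordinary percent coefficient of variation (sample SD over mean).
        """
        if len(self.ods) < 2:
            return None
        m = self.mean_od
        if m == 0:
            return 0.0
        if len(self.ods) == 2:
            return 100.0 * abs(self.ods[0] - self.ods[1]) / m
        import statistics

        return 100.0 * statistics.stdev(self.ods) / m


@dataclass
class ScreenConfig:
    """All tunables of the screening chain.

    Defaults follow the alignment tool's documented protein defaults
    (BLOSUM62, gap open 14, gap extend 4, one alignment per pair) and the
    published cutoffs: at least ``min_identity`` identical residues and an
    alignment of at least ``min_length`` columns. ``strict_length`` switches
    the length rule to strictly-greater-than. IC50 thresholds follow the
    conventional strong-binder bounds of 50 nM (HLA-I) and 500 nM (HLA-II).
    ``cutoff_k`` multiplies the background SD when deriving the ELISA cutoff.
    """

    min_identity: int = 7
    min_length: int = 12
    strict_length: bool = False
    gap_open: float = 14.0
    gap_extend: float = 4.0
    matrix_name: str = "BLOSUM62"
    n_alternatives: int = 1
    hla1_ic50_max: float = 50.0
    hla2_ic50_max: float = 500.0
    cutoff_k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_identity < 1:
            raise ValueError("min_identity must be >= 1")
        if self.min_length < self.min_identity:
            raise ValueError("min_length must be >= min_identity")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.n_alternatives < 1:
            raise ValueError("n_alternatives must be >= 1")
        if self.hla1_ic50_max <= 0 or self.hla2_ic50_max <= 0:
            raise ValueError("IC50 thresholds must be positive")
        if self.cutoff_k <= 0:
            raise ValueError("cutoff_k must be positive")
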