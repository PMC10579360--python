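"""Synthetic study generator: planted-homology epitope catalogs, HLA
binding tables and ELISA panels with the statistical structure the
analysis assumes.

The generator emulates the shape of the real study inputs so that every
pipeline stage is testable offline with known ground truth:

* a random target protein (default 331 residues, the length of the
  microbial transglutaminase target), residues drawn i.i.d. from natural
  amino-acid frequencies;
* ``n_planted`` epitopes that are contiguous target substrings with exactly
  ``planted_mutations`` interior positions substituted by residues scoring
  non-positively (but bounded below, see :func:`plant_epitopes`) against
  the original, so identity and similarity of the recovered alignment are
  known analytically;
* ``n_background`` epitopes with no planted similarity, drawn i.i.d. from
  the same residue frequencies with lengths in ``background_length_range``
  (default 8-12, the typical linear-epitope range; kept at or below the
  12-column length cutoff so a background epitope essentially cannot pass
  the identity/length stage by chance);
* an ELISA panel of ``n_antigens`` (default 77) with a dominant
  near-background OD cluster (Normal(0.16, 0.12^2) truncated at 0 by
  default) and ``n_reactive`` antigens shifted upward, duplicate wells
  jittered to keep their CV under 7%;
* a binding table whose IC50 values are log-uniform over [2, 50000] nM,
  with a configurable share forced under the strong-binder threshold.

Every generator is a pure function of the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrices import SubstitutionMatrix, load_matrix
from .types import (
    AMINO_ACIDS,
    DISEASE_VOCABULARY,
    BindingRecord,
    ELISAMeasurement,
    Epitope,
    ProteinSequence,
)

__all__ = [
    "SyntheticSpec",
    "PlantedEpitope",
    "StudyBundle",
    "gen_target_protein",
    "plant_epitopes",
    "gen_background_epitopes",
    "gen_binding_table",
    "gen_elisa_panel",
    "generate_study",
    "write_study",
]

#: Approximate natural amino-acid frequencies (percent), used for both the
#: target protein and background epitopes.
BACKGROUND_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.65, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.85,
}

_LETTERS = list(BACKGROUND_FREQUENCIES)
_PROBS = np.array([BACKGROUND_FREQUENCIES[c] for c in _LETTERS])
_PROBS = _PROBS / _PROBS.sum()

_HLA1_ALLELES = ("HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02", "HLA-B*08:01")
_HLA2_ALLELES = ("HLA-DRB1*01:01", "HLA-DRB1*04:01", "HLA-DRB1*15:01")

# Mutations are confined to interior positions, at least this many residues
# from either end of the planted segment, and substitutes score no worse
# than -3; together these keep every prefix/suffix of the segment positively
# scoring, so the segment's optimal local alignment to its source window is
# the full ungapped window and recovery is analytic, not statistical.
_EDGE_MARGIN = 3
_WORST_SUBSTITUTE = -3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study; every default is a study condition."""

    seed: int = 0
    target_length: int = 331
    n_background: int = 200
    background_length_range: tuple[int, int] = (8, 12)
    n_planted: int = 5
    planted_length: int = 15
    planted_mutations: int = 3
    n_antigens: int = 77
    n_reactive: int = 20
    bg_od_mean: float = 0.16
    bg_od_sd: float = 0.12
    reactive_od_shift: float = 0.30
    binding_fraction_strong: float = 0.5
    n_planted_strong: int = 4
    n_planted_reactive: int = 3
    antibody: str = "polyclonal"

    def __post_init__(self) -> None:
        if self.planted_mutations >= self.planted_length:
            raise ValueError("planted_mutations must be < planted_length")
        if self.planted_length > self.target_length:
            raise ValueError("planted_length exceeds target_length")
        if self.n_reactive > self.n_antigens:
            raise ValueError("n_reactive exceeds n_antigens")
        if self.n_planted > self.n_antigens:
            raise ValueError("n_planted exceeds n_antigens")
        if self.n_planted_reactive > min(self.n_planted, self.n_reactive):
            raise ValueError("n_planted_reactive too large")
        if self.n_planted_strong > self.n_planted:
            raise ValueError("n_planted_strong exceeds n_planted")
        interior = self.planted_length - 2 * _EDGE_MARGIN
        if self.planted_mutations > max(interior, 0):
            raise ValueError(
                f"planted_length {self.planted_length} has only "
                f"{max(interior, 0)} interior positions for "
                f"{self.planted_mutations} mutations"
            )
        if not (0 <= self.binding_fraction_strong <= 1):
            raise ValueError("binding_fraction_strong must be in [0, 1]")
        lo, hi = self.background_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid background_length_range")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([spec.seed, stream])


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_LETTERS, size=n, p=_PROBS))


@dataclass(frozen=True)
class PlantedEpitope:
    """A planted epitope with its ground truth."""

    epitope: Epitope
    start: int  # 1-based start of the source window on the target
    source_peptide: str  # the unmutated target substring
    mutated_positions: tuple[int, ...]  # 0-based within the segment


def gen_target_protein(spec: SyntheticSpec) -> ProteinSequence:
    """A random target protein; deterministic given the spec's seed."""
    rng = _rng(spec, 0)
    return ProteinSequence(
        id="SYN-TARGET",
        residues=_random_residues(rng, spec.target_length),
        name="synthetic target protein (microbial transglutaminase stand-in)",
    )


def plant_epitopes(
    target: ProteinSequence,
    spec: SyntheticSpec,
    matrix: SubstitutionMatrix | None = None,
) -> list[PlantedEpitope]:
    """Plant mutated copies of target segments as epitopes.

    Each planted epitope copies a contiguous ``planted_length`` window of
    the target and substitutes exactly ``planted_mutations`` distinct
    interior positions with residues scoring in [-3, 0] against the
    original under BLOSUM62, so the ungapped identity to the source window
    is ``planted_length - planted_mutations`` by construction and the
    mutated columns are never counted as similar. Windows do not overlap.
    """
    if matrix is None:
        matrix = load_matrix()
    if spec.planted_length > len(target):
        raise ValueError("planted_length exceeds target length")
    rng = _rng(spec, 1)
    L = spec.planted_length
    n_slots = len(target) // L
    if spec.n_planted > n_slots:
        raise ValueError("target too short for non-overlapping planted windows")
    slots = rng.choice(n_slots, size=spec.n_planted, replace=False)
    slots.sort()
    out = []
    for i, slot in enumerate(slots):
        start = int(slot) * L  # 0-based
        source = target.residues[start : start + L]
        positions = rng.choice(
            np.arange(_EDGE_MARGIN, L - _EDGE_MARGIN),
            size=spec.planted_mutations,
            replace=False,
        )
        positions = tuple(sorted(int(p) for p in positions))
        residues = list(source)
        for p in positions:
            orig = residues[p]
            candidates = [
                b
                for b in AMINO_ACIDS
                if b != orig and _WORST_SUBSTITUTE <= matrix.score(orig, b) <= 0
            ]
            residues[p] = str(rng.choice(candidates))
        diseases = frozenset(
            rng.choice(DISEASE_VOCABULARY, size=int(rng.integers(1, 3)),
                       replace=False)
        )
        out.append(
            PlantedEpitope(
                epitope=Epitope(
                    epitope_id=f"PLANTED-{i + 1:03d}",
                    sequence="".join(residues),
                    parent_antigen=f"synthetic planted antigen {i + 1}",
                    antigen_accession=f"SYNP{i + 1:04d}",
                    diseases=diseases,
                    assay_classes=frozenset({"T cell", "B cell"}),
                ),
                start=start + 1,
                source_peptide=source,
                mutated_positions=positions,
            )
        )
    return out


def gen_background_epitopes(
    spec: SyntheticSpec, antigen_names: list[str] | None = None
) -> list[Epitope]:
    """Background epitopes with no planted similarity.

    Sequences are i.i.d. draws from the natural residue frequencies with
    lengths uniform over ``background_length_range``; disease tags are
    decoys sampled from the controlled vocabulary; parent antigens are
    drawn from ``antigen_names`` when given.
    """
    rng = _rng(spec, 2)
    lo, hi = spec.background_length_range
    out = []
    for i in range(spec.n_background):
        length = int(rng.integers(lo, hi + 1))
        n_dis = int(rng.integers(0, 3))
        diseases = frozenset(
            rng.choice(DISEASE_VOCABULARY, size=n_dis, replace=False)
        )
        if antigen_names:
            parent = str(rng.choice(antigen_names))
        else:
            parent = f"synthetic background antigen {i + 1}"
        out.append(
            Epitope(
                epitope_id=f"BG-{i + 1:05d}",
                sequence=_random_residues(rng, length),
                parent_antigen=parent,
                diseases=diseases,
                assay_classes=frozenset({"B cell"}),
            )
        )
    return out


def gen_binding_table(
    peptides: list[str],
    spec: SyntheticSpec,
    strong: dict[str, bool] | None = None,
    hla1_max: float = 50.0,
    hla2_max: float = 500.0,
) -> list[BindingRecord]:
    """Predicted IC50 records for the given peptides.

    Each peptide receives one class-I and one class-II record. IC50 values
    are log-uniform over [2, 50000] nM; a peptide designated strong (via
    ``strong``, else a Bernoulli(``binding_fraction_strong``) draw) has its
    best record forced under the class threshold, a weak peptide has both
    records forced above 10x the class threshold.
    """
    rng = _rng(spec, 3)
    out = []
    for pep in peptides:
        is_strong = (
            strong[pep]
            if strong is not None and pep in strong
            else bool(rng.random() < spec.binding_fraction_strong)
        )
        strong_class = str(rng.choice(["I", "II"]))
        for cls, alleles, cap in (
            ("I", _HLA1_ALLELES, hla1_max),
            ("II", _HLA2_ALLELES, hla2_max),
        ):
            if is_strong and cls == strong_class:
                lo, hi = 2.0, cap
            else:
                lo, hi = 10.0 * cap, 50000.0
            ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            out.append(
                BindingRecord(
                    peptide=pep,
                    allele=str(rng.choice(alleles)),
                    hla_class=cls,
                    ic50_nM=min(ic50, 50000.0),
                )
            )
    return out


def gen_elisa_panel(
    spec: SyntheticSpec,
    pinned_means: dict[str, float] | None = None,
    antigen_names: list[str] | None = None,
) -> tuple[list[ELISAMeasurement], set[str]]:
    """An OD panel: dominant near-background cluster plus reactive antigens.

    Returns ``(measurements, designed reactive antigen names)``. The first
    ``n_reactive`` antigens are reactive (background draw plus
    ``reactive_od_shift``); all ODs are truncated at 0; duplicate wells are
    jittered multiplicatively so their CV stays below 7%. ``pinned_means``
    fixes chosen antigens' mean ODs exactly (used to keep designed ground
    truth stable; see methods note).
    """
    rng = _rng(spec, 4)
    if antigen_names is None:
        antigen_names = [f"AG{i + 1:03d}" for i in range(spec.n_antigens)]
    if len(antigen_names) != spec.n_antigens:
        raise ValueError("antigen_names length must equal n_antigens")
    reactive = set(antigen_names[: spec.n_reactive])
    measurements = []
    for name in antigen_names:
        if pinned_means and name in pinned_means:
            mean = pinned_means[name]
        else:
            mean = rng.normal(spec.bg_od_mean, spec.bg_od_sd)
            if name in reactive:
                mean += spec.reactive_od_shift
        mean = max(mean, 0.005)
        delta = rng.uniform(0.0, 0.06)
        od1 = mean * (1 + delta / 2)
        od2 = mean * (1 - delta / 2)
        measurements.append(
            ELISAMeasurement(
                antigen=name, antibody=spec.antibody, ods=(od1, od2)
            )
        )
    return measurements, reactive


@dataclass(frozen=True)
class StudyBundle:
    """A complete synthetic study with its ground truth."""

    spec: SyntheticSpec
    target: ProteinSequence
    planted: tuple[PlantedEpitope, ...]
    epitopes: tuple[Epitope, ...]  # planted first, then background
    binding_records: tuple[BindingRecord, ...]
    elisa: tuple[ELISAMeasurement, ...]
    designed_reactive: frozenset[str]
    truth_planted_ids: frozenset[str]  # pass identity/length stage
    truth_final_ids: frozenset[str]  # survive all three filters
    extras: dict = field(default_factory=dict)


def generate_study(spec: SyntheticSpec) -> StudyBundle:
    """Assemble a full synthetic study wired for end-to-end screening.

    Planted epitope ``i`` (0-based) is assigned a strong-binding target
    peptide iff ``i < n_planted_strong`` and a cross-reactive parent
    antigen iff ``i < n_planted_reactive``, so the epitopes expected to
    survive the whole filter chain are exactly the first
    ``min(n_planted_strong, n_planted_reactive)`` planted ones. Parent
    antigens of planted epitopes have their panel ODs pinned to the middle
    of their designed class so the designed truth is stable under the
    background-trimming cutoff.
    """
    target = gen_target_protein(spec)
    planted = plant_epitopes(target, spec)
    rng = _rng(spec, 5)

    # panel antigen names: planted parents first among reactive/non-reactive
    planted_parents = [p.epitope.parent_antigen for p in planted]
    n_generic = spec.n_antigens - spec.n_planted
    generic = [f"AG{i + 1:03d}" for i in range(n_generic)]
    reactive_names = (
        planted_parents[: spec.n_planted_reactive]
        + generic[: spec.n_reactive - spec.n_planted_reactive]
    )
    nonreactive_names = (
        planted_parents[spec.n_planted_reactive :]
        + generic[spec.n_reactive - spec.n_planted_reactive :]
    )
    antigen_names = reactive_names + nonreactive_names

    pinned = {}
    for i, parent in enumerate(planted_parents):
        if i < spec.n_planted_reactive:
            mean = spec.bg_od_mean + spec.reactive_od_shift
        else:
            mean = spec.bg_od_mean
        pinned[parent] = float(
            max(rng.normal(mean, spec.bg_od_sd / 4), 0.005)
        )
    elisa, designed_reactive = gen_elisa_panel(
        spec, pinned_means=pinned, antigen_names=antigen_names
    )

    background = gen_background_epitopes(
        spec, antigen_names=[n for n in generic]
    )

    strong = {
        p.source_peptide: (i < spec.n_planted_strong)
        for i, p in enumerate(planted)
    }
    decoys = []
    for _ in range(20):
        start = int(rng.integers(0, len(target) - spec.planted_length))
        decoys.append(target.residues[start : start + spec.planted_length])
    peptides = [p.source_peptide for p in planted] + decoys
    binding = gen_binding_table(peptides, spec, strong=strong)

    truth_planted = frozenset(p.epitope.epitope_id for p in planted)
    n_final = min(spec.n_planted_strong, spec.n_planted_reactive)
    truth_final = frozenset(
        p.epitope.epitope_id for p in planted[:n_final]
    )
    return StudyBundle(
        spec=spec,
        target=target,
        planted=tuple(planted),
        epitopes=tuple([p.epitope for p in planted] + background),
        binding_records=tuple(binding),
        elisa=tuple(elisa),
        designed_reactive=frozenset(designed_reactive),
        truth_planted_ids=truth_planted,
        truth_final_ids=truth_final,
    )


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a study bundle to disk in the formats the pipeline reads.

    Produces ``target.fasta``, ``epitopes.tsv``, ``binding.tsv``,
    ``elisa.tsv``, a ready pipeline ``config.yaml`` and a
    ``ground_truth.json`` (synthetic labels, for evaluation only). Returns
    the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = outdir / "target.fasta"
    fasta.write_text(f">{bundle.target.id} {bundle.target.name}\n"
                     + bundle.target.residues + "\n")
    paths["target"] = fasta

    ep = outdir / "epitopes.tsv"
    pd.DataFrame(
        [
            {
                "epitope_id": e.epitope_id,
                "sequence": e.sequence,
                "parent_antigen": e.parent_antigen,
                "antigen_accession": e.antigen_accession or "",
                "diseases": ";".join(sorted(e.diseases)),
                "assay_classes": ";".join(sorted(e.assay_classes)),
                "outcome": "Positive",
            }
            for e in bundle.epitopes
        ]
    ).to_csv(ep, sep="\t", index=False)
    paths["epitopes"] = ep

    bt = outdir / "binding.tsv"
    pd.DataFrame(
        [
            {
                "peptide": r.peptide,
                "allele": r.allele,
                "hla_class": r.hla_class,
                "ic50_nM": f"{r.ic50_nM:.4f}",
            }
            for r in bundle.binding_records
        ]
    ).to_csv(bt, sep="\t", index=False)
    paths["binding"] = bt

    el = outdir / "elisa.tsv"
    pd.DataFrame(
        [
            {
                "antigen": m.antigen,
                "antibody": m.antibody,
                "od1": f"{m.ods[0]:.6f}",
                "od2": f"{m.ods[1]:.6f}",
            }
            for m in bundle.elisa
        ]
    ).to_csv(el, sep="\t", index=False)
    paths["elisa"] = el

    cfg = outdir / "config.yaml"
    cfg.write_text(
        yaml.safe_dump(
            {
                "inputs": {
                    "target": str(fasta),
                    "epitopes": str(ep),
                    "binding": str(bt),
                    "elisa": str(el),
                },
                "screen": {"seed": bundle.spec.seed},
                "output_dir": str(outdir / "results"),
            },
            sort_keys=True,
        )
    )
    paths["config"] = cfg

    gt = outdir / "ground_truth.json"
    gt.write_text(
        json.dumps(
            {
                "_note": "synthetic ground-truth labels for evaluation only",
                "planted_ids": sorted(bundle.truth_planted_ids),
                "final_hit_ids": sorted(bundle.truth_final_ids),
                "designed_reactive": sorted(bundle.designed_reactive),
                "planted_starts": {
                    p.epitope.epitope_id: p.start for p in bundle.planted
                },
            },
            indent=2,
            sort_keys=True,
        )
    )
    paths["ground_truth"] = gt
    return paths
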