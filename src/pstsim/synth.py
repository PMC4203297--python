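"""Synthetic multilocus datasets emulating the 14-locus two-species
study design, so the summary, observed-arm and test stages run end to end
without the (undeposited) real sequences.

A dataset is generated under one of the isolation models: per locus, a
gene tree with the study's per-locus sample sizes is simulated and a
nucleotide matrix of the study's locus length evolved along it, with the
branch scaling calibrated so simulated divergence matches the observed
target.  Haplotypes are paired into diploid individuals in sampling order
for the heterozygosity statistics.  A truth record (master seed, per-
locus seeds and scalings) makes every dataset byte-identical to
regenerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .datasets import observed_between_divergence, uma_locus_table, uma_mutation_rates
from .models import POP1, POP2, IsolationModel, simulate_gene_tree
from .seqsim import (
    LocusAlignment,
    ScalingFactor,
    SubstitutionModel,
    calibrate_scaling,
    evolve_sequences,
    write_fasta,
    write_popmap,
)

__all__ = [
    "LocusSpec",
    "SyntheticDataset",
    "default_locus_specs",
    "generate_dataset",
]

#: population identifiers used in synthetic popmaps: group 1 is the
#: *U. notata*-complex side, group 2 the *U. scoparia* side.
GROUP1 = "notata"
GROUP2 = "scoparia"


@dataclass(frozen=True)
class LocusSpec:
    """Design of one locus: length, per-group sample sizes and the
    assumed per-year mutation rate."""

    name: str
    length: int
    n_group1: int
    n_group2: int
    mutation_rate: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("locus length must be positive")
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("need at least two sequences per group")
        if self.mutation_rate <= 0:
            raise ValueError("mutation rate must be positive")


def default_locus_specs() -> list[LocusSpec]:
    """The study's 14 loci with their published lengths, per-group phased
    sample sizes, and assumed mutation rates."""
    table = uma_locus_table()
    rates = uma_mutation_rates()
    return [
        LocusSpec(
            name=row.locus,
            length=int(row.L),
            n_group1=int(row.n_notata),
            n_group2=int(row.n_scoparia),
            mutation_rate=rates[row.locus],
        )
        for row in table.itertuples()
    ]


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus the truth record needed to
    regenerate it exactly."""

    model_label: str
    alignments: list[LocusAlignment]
    populations: dict[str, str]
    diploid_pairs: list[tuple[str, str, str]]  # (individual, hap_a, hap_b)
    truth: dict

    def write(self, out_dir) -> None:
        """Write per-locus FASTA files, the population map, the diploid
        pairing table and the truth record."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in self.alignments:
            write_fasta(aln, out / f"{aln.name}.fasta")
        write_popmap(self.populations, out / "popmap.tsv")
        with open(out / "diploid_pairs.tsv", "w") as fh:
            fh.write("individual\thaplotype_a\thaplotype_b\n")
            for ind, a, b in self.diploid_pairs:
                fh.write(f"{ind}\t{a}\t{b}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _sample_labels(n1: int, n2: int) -> list[str]:
    return [f"{GROUP1}_{i:03d}" for i in range(n1)] + [
        f"{GROUP2}_{i:03d}" for i in range(n2)
    ]


def generate_dataset(
    model: IsolationModel,
    specs: Optional[Sequence[LocusSpec]] = None,
    target_divergence: Optional[float] = None,
    seed: int = 0,
    sub_model: Optional[SubstitutionModel] = None,
    scaling: Optional[ScalingFactor] = None,
    calibration_pairs: str = "between",
    out_dir=None,
) -> SyntheticDataset:
    """Generate a complete synthetic dataset under ``model``.

    One branch-scaling factor is calibrated for the model (reused across
    loci, recorded per locus in the truth record); each locus then gets
    an independent gene tree and alignment from seeds derived from the
    master ``seed``.  Pass ``scaling`` to skip calibration (e.g. when
    generating many replicate datasets under one model).
    """
    specs = list(specs) if specs is not None else default_locus_specs()
    sub_model = sub_model or SubstitutionModel()
    if target_divergence is None:
        target_divergence = observed_between_divergence()
    if scaling is None:
        scaling = calibrate_scaling(
            model,
            target_divergence,
            reps=8,
            seed=seed + 40_009,
            sub_model=sub_model,
            pairs=calibration_pairs,
        ).scaling

    alignments: list[LocusAlignment] = []
    populations: dict[str, str] = {}
    truth_loci = {}
    for k, spec in enumerate(specs):
        tree_seed = (seed + 1000 * (k + 1)) % (2**31 - 1)
        seq_seed = (seed + 1000 * (k + 1) + 500_000_003) % (2**31 - 1)
        tree = simulate_gene_tree(model, spec.n_group1, spec.n_group2, tree_seed)
        aln = evolve_sequences(
            tree, spec.length, sub_model, scaling, seed=seq_seed
        )
        labels = _sample_labels(spec.n_group1, spec.n_group2)
        pops = {
            lab: (GROUP1 if i < spec.n_group1 else GROUP2)
            for i, lab in enumerate(labels)
        }
        aln = LocusAlignment(aln.matrix, labels, pops, name=spec.name)
        alignments.append(aln)
        populations.update(pops)
        truth_loci[spec.name] = {
            "tree_seed": tree_seed,
            "sequence_seed": seq_seed,
            "scaling_rate": scaling.rate,
            "length": spec.length,
            "n_group1": spec.n_group1,
            "n_group2": spec.n_group2,
        }

    # diploid pairing: consecutive same-population haplotypes form an
    # individual (exchangeability makes the order immaterial); an odd
    # haplotype at the end of a group is left unpaired.
    diploid_pairs: list[tuple[str, str, str]] = []
    for group in (GROUP1, GROUP2):
        haps = sorted(lab for lab, p in populations.items() if p == group)
        for j in range(0, len(haps) - 1, 2):
            diploid_pairs.append(
                (f"{group}_ind_{j // 2:03d}", haps[j], haps[j + 1])
            )

    truth = {
        "model": model.label,
        "master_seed": seed,
        "target_divergence": target_divergence,
        "calibration_pairs": calibration_pairs,
        "kappa": sub_model.kappa,
        "base_freqs": list(sub_model.base_freqs),
        "loci": truth_loci,
    }
    dataset = SyntheticDataset(
        model_label=model.label,
        alignments=alignments,
        populations=populations,
        diploid_pairs=diploid_pairs,
        truth=truth,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
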