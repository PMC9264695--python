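"""Synthetic candidate-father panels and Mendelian half-sib offspring.

The generator emulates a clonally propagated germplasm collection typed at
genome-wide biallelic SNPs: a set of unrelated founders drawn from
Hardy-Weinberg proportions at per-marker allele frequencies, optionally
extended with full-sib families and parent-offspring chains — the close
relatives that make exclusion-based parentage hard. Markers are placed on a
fixed karyotype (default 17 chromosomes, mirroring a typical apple-like
genome) at distinct positions. All loci are simulated unlinked (linkage
equilibrium), and the maternal parent is homozygous for the reference allele
everywhere, so dosages count the non-maternal allele and an offspring's
dosage equals its paternal gamete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel, MarkerMap

__all__ = [
    "SyntheticPanelSpec",
    "OffspringSet",
    "generate_panel",
    "simulate_offspring",
    "simulate_study_offspring",
    "mask_genotypes",
]

#: default karyotype: 17 chromosomes of 35 Mb
DEFAULT_CHROM_LENGTHS = tuple([35_000_000] * 17)


@dataclass
class SyntheticPanelSpec:
    """Recipe for a synthetic candidate-father panel.

    ``family_blocks`` lists (kind, size) with kind "full-sib" (size offspring
    of two founders) or "chain" (a parent-offspring chain: each member is a
    cross of the previous member with a random founder). ``maf`` is either
    ("uniform", lo, hi) or ("beta", a, b), in both cases confined to
    [0.05, 0.5].
    """

    n_founders: int = 40
    n_markers: int = 1000
    maf: tuple = ("uniform", 0.05, 0.5)
    family_blocks: list[tuple[str, int]] = field(
        default_factory=lambda: [("full-sib", 20), ("chain", 5)]
    )
    chrom_lengths: tuple[int, ...] = DEFAULT_CHROM_LENGTHS
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return self.n_founders + sum(size for _, size in self.family_blocks)


def _sample_mafs(spec: SyntheticPanelSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.maf[0]
    if kind == "uniform":
        lo, hi = float(spec.maf[1]), float(spec.maf[2])
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("uniform maf bounds must satisfy 0.05 <= lo <= hi <= 0.5")
        return rng.uniform(lo, hi, size=spec.n_markers)
    if kind == "beta":
        a, b = float(spec.maf[1]), float(spec.maf[2])
        if a <= 0 or b <= 0:
            raise ValueError("beta maf parameters must be positive")
        return 0.05 + 0.45 * rng.beta(a, b, size=spec.n_markers)
    raise ValueError(f"unknown maf distribution {kind!r}")


def _gamete(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Mendelian gamete per marker from a diploid dosage vector.

    Homozygotes transmit deterministically; heterozygotes transmit either
    allele with probability 1/2; missing loci transmit missing.
    """
    g = np.where(dosage == 2.0, 1.0, 0.0)
    het = dosage == 1.0
    g[het] = rng.integers(0, 2, size=int(het.sum())).astype(float)
    g[np.isnan(dosage)] = np.nan
    return g


def _cross(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return _gamete(p1, rng) + _gamete(p2, rng)


def generate_panel(spec: SyntheticPanelSpec) -> tuple[GenotypePanel, MarkerMap]:
    """Draw a panel and marker map deterministically from ``spec.seed``.

    Founders follow Hardy-Weinberg at each marker's sampled allele frequency;
    family members arise by Mendelian transmission from named parents,
    independently across markers.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = _sample_mafs(spec, rng)
    m = spec.n_markers

    founders = rng.binomial(2, mafs, size=(spec.n_founders, m)).astype(float)
    ids = [f"F{i:03d}" for i in range(spec.n_founders)]
    rows = [founders]

    for b, (kind, size) in enumerate(spec.family_blocks):
        if size <= 0:
            raise ValueError("family block size must be positive")
        if kind == "full-sib":
            pa, pb = rng.choice(spec.n_founders, size=2, replace=False)
            kids = np.stack(
                [_cross(founders[pa], founders[pb], rng) for _ in range(size)]
            )
            rows.append(kids)
            ids += [f"S{b}_{i:03d}" for i in range(size)]
        elif kind == "chain":
            prev = founders[rng.integers(spec.n_founders)]
            kids = []
            for i in range(size):
                mate = founders[rng.integers(spec.n_founders)]
                child = _cross(prev, mate, rng)
                kids.append(child)
                prev = child
            rows.append(np.stack(kids))
            ids += [f"C{b}_{i:03d}" for i in range(size)]
        else:
            raise ValueError(f"unknown family block kind {kind!r}")

    dosages = np.vstack(rows)
    marker_ids = [f"M{k:05d}" for k in range(m)]

    # markers in contiguous blocks along the karyotype, distinct positions
    n_chrom = len(spec.chrom_lengths)
    chrom_labels = [f"chr{c + 1:02d}" for c in range(n_chrom)]
    per = np.full(n_chrom, m // n_chrom)
    per[: m % n_chrom] += 1
    chromosome, position = {}, {}
    k = 0
    for c, label in enumerate(chrom_labels):
        length = int(spec.chrom_lengths[c])
        pos = set()
        while len(pos) < per[c]:
            pos.update(rng.integers(1, length + 1, size=per[c] - len(pos)).tolist())
        for p in sorted(pos):
            chromosome[marker_ids[k]] = label
            position[marker_ids[k]] = int(p)
            k += 1
    mmap = MarkerMap(
        chromosome=chromosome,
        position=position,
        chromosome_length=dict(zip(chrom_labels, map(int, spec.chrom_lengths))),
    )

    panel = GenotypePanel(
        individual_ids=ids,
        marker_ids=marker_ids,
        dosages=dosages,
        maternal_id="MOTHER",
        maternal_dosages=np.zeros(m),
    )
    return panel, mmap


@dataclass
class OffspringSet:
    """Simulated half-sib offspring with their true fathers.

    Offspring dosages live in {0, 1} (the paternal gamete; the mother always
    contributes 0) or nan once masked.
    """

    offspring_ids: list[str]
    true_father: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    masking_rate: float = 0.0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.offspring_ids), len(self.marker_ids)):
            raise ValueError("offspring dosage matrix shape mismatch")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("offspring dosages must be 0, 1, or missing")

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_ids)


def simulate_offspring(
    father: np.ndarray,
    n_offspring: int,
    seed: int,
    marker_ids: list[str],
    father_id: str = "father",
) -> OffspringSet:
    """Mendelian offspring of a homozygous-0 mother and one candidate father.

    Each offspring's dosage at a marker is the paternal gamete: 0 if the
    father is 0, 1 if 2, Bernoulli(1/2) if heterozygous, missing if missing —
    independent across markers and offspring (linkage equilibrium).
    """
    rng = np.random.default_rng(seed)
    father = np.asarray(father, dtype=float)
    kids = np.stack([_gamete(father, rng) for _ in range(n_offspring)])
    return OffspringSet(
        offspring_ids=[f"{father_id}_o{i}" for i in range(n_offspring)],
        true_father=[father_id] * n_offspring,
        marker_ids=list(marker_ids),
        dosages=kids,
    )


def simulate_study_offspring(
    panel: GenotypePanel, n_per_father: int = 5, seed: int = 0
) -> OffspringSet:
    """Five (by default) offspring per candidate father, as one set."""
    parts = [
        simulate_offspring(
            panel.dosages[i],
            n_per_father,
            seed=(seed + 31 * i) % (2**31 - 1),
            marker_ids=panel.marker_ids,
            father_id=fid,
        )
        for i, fid in enumerate(panel.individual_ids)
    ]
    return OffspringSet(
        offspring_ids=[oid for p in parts for oid in p.offspring_ids],
        true_father=[f for p in parts for f in p.true_father],
        marker_ids=list(panel.marker_ids),
        dosages=np.vstack([p.dosages for p in parts]),
    )


def mask_genotypes(offspring: OffspringSet, rate: float, seed: int) -> OffspringSet:
    """Set each offspring genotype missing independently with probability rate.

    Mimics failed genotyping calls (no wrong-call error model). Rates above
    20% fall outside the intended range and trigger a warning only.
    """
    if rate < 0 or rate > 1:
        raise ValueError("masking rate must be in [0, 1]")
    if rate > 0.2:
        warnings.warn(f"masking rate {rate} exceeds the intended 0-20% range")
    rng = np.random.default_rng(seed)
    dosages = offspring.dosages.copy()
    if rate > 0:
        mask = rng.random(dosages.shape) < rate
        dosages[mask] = np.nan
    realized = float(np.isnan(dosages).mean())
    return OffspringSet(
        offspring_ids=list(offspring.offspring_ids),
        true_father=list(offspring.true_father),
        marker_ids=list(offspring.marker_ids),
        dosages=dosages,
        masking_rate=realized,
    )
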