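"""Core genotype containers: the candidate-father dosage panel and the marker map.

The panel is oriented so that every dosage counts the allele *not* carried by
the (homozygous) maternal parent: the mother is dosage 0 at every retained
marker, and an offspring's dosage equals its paternal gamete. Missing calls
are stored as ``numpy.nan`` in a float matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = np.nan

__all__ = ["GenotypePanel", "MarkerMap", "MISSING"]


def _check_dosage_matrix(dosages: np.ndarray) -> None:
    finite = dosages[~np.isnan(dosages)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise ValueError(
            f"dosage values outside {{0,1,2,missing}}: {sorted(set(bad.tolist()))[:5]}"
        )


@dataclass
class GenotypePanel:
    """Allele-dosage matrix of the n candidate fathers at m biallelic markers.

    Attributes
    ----------
    individual_ids:
        The candidate paternal parents (mother excluded unless explicitly
        re-added for selfing scenarios).
    marker_ids:
        Retained marker identifiers, in panel column order.
    dosages:
        Float array of shape (n, m); entries in {0, 1, 2} or nan for missing.
        Entry [i, k] is the count of the non-maternal allele in individual i
        at marker k.
    maternal_id:
        Identifier of the known maternal parent.
    maternal_dosages:
        The mother's oriented dosages (all zero after loading/orientation).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    maternal_id: str
    maternal_dosages: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if len(self.individual_ids) < 2:
            raise ValueError("need at least two candidate fathers to discriminate")
        _check_dosage_matrix(self.dosages)
        if self.maternal_dosages is None:
            self.maternal_dosages = np.zeros(len(self.marker_ids))
        else:
            self.maternal_dosages = np.asarray(self.maternal_dosages, dtype=float)
            if self.maternal_dosages.shape != (len(self.marker_ids),):
                raise ValueError("maternal dosage vector length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_indices(self, marker_ids: list[str]) -> np.ndarray:
        lookup = {mk: k for k, mk in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[mk] for mk in marker_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"marker {exc.args[0]!r} not in panel") from None

    def subset_markers(self, keep: np.ndarray) -> "GenotypePanel":
        """New panel restricted to marker columns ``keep`` (indices or bool mask)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[k] for k in keep],
            dosages=self.dosages[:, keep],
            maternal_id=self.maternal_id,
            maternal_dosages=self.maternal_dosages[keep],
        )


@dataclass
class MarkerMap:
    """Physical positions of markers and per-chromosome lengths (base pairs)."""

    chromosome: dict[str, str]
    position: dict[str, int]
    chromosome_length: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.chromosome) != set(self.position):
            raise ValueError("chromosome and position maps cover different markers")
        for chrom, length in self.chromosome_length.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom!r}")
        for mk, chrom in self.chromosome.items():
            pos = self.position[mk]
            if pos < 0:
                raise ValueError(f"negative position for marker {mk!r}")
            if chrom in self.chromosome_length and pos > self.chromosome_length[chrom]:
                raise ValueError(
                    f"marker {mk!r} at {pos} beyond chromosome {chrom!r} "
                    f"length {self.chromosome_length[chrom]}"
                )

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.chromosome

    def unmapped(self, marker_ids: list[str]) -> list[str]:
        return [mk for mk in marker_ids if mk not in self.chromosome]
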