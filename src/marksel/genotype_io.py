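"""Reading genotype panels, dataset-construction filters, and Cervus export.

Loading orients every marker on the maternal parent: only biallelic SNPs at
which the mother is a non-missing homozygote are retained, and dosages are
recoded as counts of the allele she does not carry, so her oriented dosage is
0 everywhere. Markers are then thinned the way a practitioner prepares a
panel for parentage work: a minor-allele-frequency floor, a minimum physical
spacing, and a windowed LD prune on squared dosage correlation (a simplified
single-pass reimplementation of the usual PLINK-style filter — exact PLINK
replication is a non-goal).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .discrimination import MarkerSolution
from .panel import GenotypePanel, MarkerMap
from .simulate import OffspringSet

logger = logging.getLogger(__name__)

__all__ = [
    "load_panel",
    "load_marker_map",
    "filter_maf",
    "prune_spacing_ld",
    "export_cervus",
    "write_dosage_tsv",
    "write_offspring_tsv",
    "write_solution",
]

_MISSING_TOKENS = {"NA", ".", "", "nan", "NaN"}


def _orient_on_mother(
    marker_ids: list[str],
    dosages: np.ndarray,
    maternal: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    """Keep markers where the mother is a non-missing homozygote; flip so she is 0."""
    hom0 = maternal == 0.0
    hom2 = maternal == 2.0
    keep = hom0 | hom2
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d marker(s) where mother is missing or heterozygous", n_drop)
    dosages = dosages[:, keep].copy()
    flip = hom2[keep]
    dosages[:, flip] = 2.0 - dosages[:, flip]
    kept_ids = [mk for mk, k in zip(marker_ids, keep) if k]
    if not kept_ids:
        raise ValueError("no informative loci: every marker failed maternal orientation")
    return kept_ids, dosages


def _load_dosage_tsv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    marker_ids = [str(m) for m in df.index]
    sample_ids = [str(s) for s in df.columns]
    raw = df.to_numpy()
    values = np.full(raw.shape, np.nan)
    mask = ~np.isin(raw, list(_MISSING_TOKENS))
    try:
        values[mask] = raw[mask].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric dosage value in {path}: {exc}") from None
    finite = values[~np.isnan(values)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise ValueError(
            f"dosage values outside {{0,1,2,missing}} in {path}: "
            f"{sorted(set(bad.tolist()))[:5]}"
        )
    # matrix arrives markers x samples; panel stores samples x markers
    return marker_ids, sample_ids, values.T


def _load_vcf(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy + 1); last col = phased
        alleles = gts[:, :2]
        dos = alleles.sum(axis=1).astype(float)
        dos[(alleles < 0).any(axis=1)] = np.nan  # half-calls and missing
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        rows.append(dos)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP record(s)", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return marker_ids, sample_ids, np.stack(rows).T


def load_panel(
    genotype_path: str | Path,
    format: str,
    maternal_id: str,
    mother_is_candidate: bool = False,
) -> GenotypePanel:
    """Load a candidate-father panel from VCF or a dosage TSV and orient it.

    The dosage TSV has markers as rows (first column marker id) and samples
    as columns; "NA" and "." denote missing. The mother must be among the
    samples; she is removed from the candidate set unless
    ``mother_is_candidate`` (selfing scenarios).
    """
    path = Path(genotype_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dosage-tsv":
        marker_ids, sample_ids, dosages = _load_dosage_tsv(path)
    elif format == "vcf":
        marker_ids, sample_ids, dosages = _load_vcf(path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'vcf' or 'dosage-tsv'")

    if maternal_id not in sample_ids:
        raise ValueError(
            f"maternal id {maternal_id!r} not among samples {sample_ids[:10]}"
            f"{'...' if len(sample_ids) > 10 else ''}"
        )
    mi = sample_ids.index(maternal_id)
    maternal = dosages[mi]
    marker_ids, dosages = _orient_on_mother(marker_ids, dosages, maternal)
    if not mother_is_candidate:
        keep = [i for i in range(len(sample_ids)) if i != mi]
        sample_ids = [sample_ids[i] for i in keep]
        dosages = dosages[keep]
    return GenotypePanel(
        individual_ids=sample_ids,
        marker_ids=marker_ids,
        dosages=dosages,
        maternal_id=maternal_id,
        maternal_dosages=np.zeros(len(marker_ids)),
    )


def load_marker_map(map_path: str | Path, lengths_path: str | Path) -> MarkerMap:
    """Read a marker-map TSV (marker, chrom, pos) and chromosome lengths (chrom, length)."""
    mdf = pd.read_csv(map_path, sep="\t", dtype={0: str, 1: str})
    mdf.columns = ["marker", "chrom", "pos"]
    ldf = pd.read_csv(lengths_path, sep="\t", dtype={0: str})
    ldf.columns = ["chrom", "length"]
    return MarkerMap(
        chromosome=dict(zip(mdf["marker"], mdf["chrom"])),
        position={m: int(p) for m, p in zip(mdf["marker"], mdf["pos"])},
        chromosome_length={c: int(l) for c, l in zip(ldf["chrom"], ldf["length"])},
    )


def filter_maf(panel: GenotypePanel, maf_min: float) -> GenotypePanel:
    """Keep markers with minor-allele frequency >= maf_min among the fathers.

    Frequency is the dosage sum over twice the non-missing count; the minor
    allele is whichever is rarer. Marker order is preserved.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    non_missing = (~np.isnan(panel.dosages)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(panel.dosages, axis=0) / (2.0 * non_missing)
    freq = np.nan_to_num(freq, nan=0.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min
    if not keep.any():
        counts = pd.Series(np.round(maf, 3)).value_counts().to_dict()
        raise ValueError(f"maf filter removed every marker; maf distribution: {counts}")
    logger.info("maf >= %g keeps %d / %d markers", maf_min, int(keep.sum()), panel.n_markers)
    return panel.subset_markers(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over individuals non-missing in both."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0.0 or ys.std() == 0.0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def prune_spacing_ld(
    panel: GenotypePanel,
    mmap: MarkerMap,
    window: int = 50,
    r2_max: float = 0.5,
    min_bp: int = 10_000,
) -> GenotypePanel:
    """Thin markers by physical spacing and windowed LD, per chromosome.

    Scanning each chromosome in (position, marker id) order, the later marker
    of any pair closer than ``min_bp`` is removed; a surviving marker is then
    removed if its squared dosage correlation with any of the previous
    ``window - 1`` kept loci on the chromosome exceeds ``r2_max``. The pass
    is deterministic and idempotent.
    """
    unmapped = mmap.unmapped(panel.marker_ids)
    if unmapped:
        raise ValueError(f"unmapped markers: {unmapped[:10]}")
    keep = np.zeros(panel.n_markers, dtype=bool)
    order = sorted(
        range(panel.n_markers),
        key=lambda k: (
            mmap.chromosome[panel.marker_ids[k]],
            mmap.position[panel.marker_ids[k]],
            panel.marker_ids[k],
        ),
    )
    by_chrom: dict[str, list[int]] = {}
    for k in order:
        by_chrom.setdefault(mmap.chromosome[panel.marker_ids[k]], []).append(k)

    for chrom, markers in by_chrom.items():
        kept: list[int] = []
        for k in markers:
            pos = mmap.position[panel.marker_ids[k]]
            if kept and pos - mmap.position[panel.marker_ids[kept[-1]]] < min_bp:
                continue
            recent = kept[-(window - 1):] if window > 1 else []
            if any(
                _pairwise_r2(panel.dosages[:, k], panel.dosages[:, j]) > r2_max
                for j in recent
            ):
                continue
            kept.append(k)
        keep[kept] = True
    logger.info(
        "spacing/LD prune keeps %d / %d markers", int(keep.sum()), panel.n_markers
    )
    return panel.subset_markers(keep)


def write_dosage_tsv(panel: GenotypePanel, path: str | Path, include_mother: bool = False) -> None:
    """Write the panel as a markers x samples dosage TSV ("NA" for missing)."""
    data = panel.dosages.T
    cols = list(panel.individual_ids)
    if include_mother:
        data = np.column_stack([panel.maternal_dosages, data])
        cols = [panel.maternal_id] + cols
    df = pd.DataFrame(data, index=panel.marker_ids, columns=cols)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "marker"
    out.to_csv(path, sep="\t")


def write_offspring_tsv(offspring: OffspringSet, dosage_path: str | Path, truth_path: str | Path) -> None:
    df = pd.DataFrame(
        offspring.dosages.T, index=offspring.marker_ids, columns=offspring.offspring_ids
    )
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "marker"
    out.to_csv(dosage_path, sep="\t")
    pd.DataFrame(
        {"offspring": offspring.offspring_ids, "true_father": offspring.true_father}
    ).to_csv(truth_path, sep="\t", index=False)


def write_solution(
    solution: MarkerSolution,
    mmap: MarkerMap | None,
    tsv_path: str | Path,
    json_path: str | Path,
    status: str = "",
) -> None:
    """Write the selected markers (id, chrom, pos) plus a JSON metrics sidecar."""
    import json

    rows = []
    for mk in solution.selected:
        if mmap is not None and mk in mmap:
            rows.append({"marker": mk, "chrom": mmap.chromosome[mk], "pos": mmap.position[mk]})
        else:
            rows.append({"marker": mk, "chrom": "NA", "pos": "NA"})
    pd.DataFrame(rows, columns=["marker", "chrom", "pos"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    metrics = {
        "f": solution.f,
        "g": solution.g,
        "depth": solution.depth,
        "h": solution.h_used,
        "feasible": solution.feasible,
        "status": status,
    }
    Path(json_path).write_text(json.dumps(metrics, indent=2) + "\n")


_DOSAGE_ALLELES = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}


def _cervus_frame(
    ids: list[str], dosages: np.ndarray, marker_ids: list[str]
) -> pd.DataFrame:
    cols: dict[str, list[str]] = {"ID": ids}
    for k, mk in enumerate(marker_ids):
        a_col, b_col = [], []
        for v in dosages[:, k]:
            a, b = ("*", "*") if np.isnan(v) else _DOSAGE_ALLELES[v]
            a_col.append(a)
            b_col.append(b)
        cols[f"{mk}a"] = a_col
        cols[f"{mk}b"] = b_col
    return pd.DataFrame(cols)


def export_cervus(
    panel: GenotypePanel,
    offspring: OffspringSet,
    solution: MarkerSolution,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write Cervus-layout genotype CSVs for the selected markers.

    Three files: candidate fathers plus the mother, the offspring, and a
    plain list of candidate-father ids. Alleles are coded A/B per dosage
    (0 -> A,A; 1 -> A,B; 2 -> B,B; missing -> *,*) in two columns per locus.
    """
    if not solution.selected:
        raise ValueError("cannot export an empty marker solution")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pk = panel.marker_indices(solution.selected)
    off_idx = {mk: k for k, mk in enumerate(offspring.marker_ids)}
    ok = np.array([off_idx[mk] for mk in solution.selected], dtype=int)

    parent_ids = [panel.maternal_id] + list(panel.individual_ids)
    parent_dos = np.vstack([panel.maternal_dosages[pk], panel.dosages[:, pk]])
    paths = {
        "parents": out / "cervus_parents.csv",
        "offspring": out / "cervus_offspring.csv",
        "father_list": out / "candidate_fathers.txt",
    }
    _cervus_frame(parent_ids, parent_dos, solution.selected).to_csv(
        paths["parents"], index=False
    )
    _cervus_frame(
        list(offspring.offspring_ids), offspring.dosages[:, ok], solution.selected
    ).to_csv(paths["offspring"], index=False)
    paths["father_list"].write_text("\n".join(panel.individual_ids) + "\n")
    return paths
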