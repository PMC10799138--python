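"""Read/write genotype data (VCF) and genetic maps, and attach centimorgan
coordinates to markers.

Genotypes are stored as integer alternate-allele dosages in {0, 1, 2} with
``MISSING`` (-1) as sentinel. Genotype probability simplexes travel in the
VCF ``GP`` FORMAT field as linear probabilities (three comma-separated
values summing to 1); decoded priors contain exact zeros, which the
log10-scaled GL field could not represent, so GP is the primary channel and
GL is an optional extra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1

#: columns of the marker table carried by every GenotypeMatrix
MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "cm"]


class VcfValidationError(ValueError):
    """A VCF record violates the biallelic-SNP / homozygosity contract."""


class MapValidationError(ValueError):
    """A genetic map violates monotonicity or is missing a chromosome."""


@dataclass
class GenotypeMatrix:
    """Samples x markers integer dosage matrix with marker annotations.

    Parameters
    ----------
    sample_ids
        Sample names, length ``n_samples``.
    markers
        DataFrame with columns ``id, chrom, pos, ref, alt, cm``; within a
        chromosome positions are strictly increasing. ``cm`` is NaN until
        :func:`interpolate_cm` fills it.
    dosages
        ``(n_samples, n_markers)`` int array over {0, 1, 2, MISSING}.
    fully_homozygous
        When True, no entry may equal 1.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray
    fully_homozygous: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        if self.fully_homozygous and (self.dosages == 1).any():
            raise VcfValidationError("heterozygous dosage in fully homozygous matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class GeneticMap:
    """Per-chromosome anchors (physical bp, genetic cM).

    Positions are strictly increasing and cM non-decreasing within each
    chromosome.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def chromosomes(self) -> list[str]:
        return list(self.anchors)


def read_vcf(path: str, require_homozygous: bool = False) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    GT is mapped to dosage 0 (hom-ref), 1 (het), 2 (hom-alt) or MISSING
    (``./.``). With ``require_homozygous`` any heterozygote raises
    :class:`VcfValidationError`, matching the decoder's assumption that the
    input lines are fully inbred.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VcfValidationError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} (ALT={rec.ALT})"
            )
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise VcfValidationError(
                f"non-SNP record at {rec.CHROM}:{rec.POS} ({rec.REF}>{rec.ALT[0]})"
            )
        gts = np.asarray(rec.gt_types, dtype=np.int16)  # 0,1,2 dosage; 3 unknown
        dos = np.where(gts == 3, MISSING, gts)
        if require_homozygous and (dos == 1).any():
            bad = samples[int(np.argmax(dos == 1))]
            raise VcfValidationError(
                f"heterozygote at {rec.CHROM}:{rec.POS} (sample {bad}) "
                "but homozygosity is required"
            )
        rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "cm": np.nan,
            }
        )
        dosage_cols.append(dos)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    _check_sorted(markers)
    dosages = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        markers=markers,
        dosages=dosages.astype(np.int16),
        fully_homozygous=require_homozygous,
    )


def _check_sorted(markers: pd.DataFrame) -> None:
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise VcfValidationError(
                f"marker positions not strictly increasing on chromosome {chrom}"
            )


def _gt_and_gp(simplex: np.ndarray) -> tuple[tuple, tuple]:
    """GT call + rounded GP triple from one probability simplex.

    GT is the argmax genotype; when the maximum is not unique (e.g. the
    undecided prior (0.5, 0, 0.5)) GT is ``./.`` while GP keeps the full
    information.
    """
    p = np.asarray(simplex, dtype=float)
    if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
        raise VcfValidationError(f"genotype simplex not normalized: {p.tolist()}")
    gp = tuple(round(float(x), 6) for x in p)
    top = p.max()
    if (np.isclose(p, top, rtol=0, atol=1e-12)).sum() > 1:
        return (None, None), gp
    g = int(np.argmax(p))
    gt = [(0, 0), (0, 1), (1, 1)][g]
    return gt, gp


def write_vcf(
    path: str,
    sample_ids: Sequence[str],
    markers: pd.DataFrame,
    dosages: np.ndarray | None = None,
    posteriors: np.ndarray | None = None,
    phased: bool = False,
    emit_gl: bool = False,
) -> str:
    """Write dosages and/or genotype-probability simplexes to a VCF 4.2 file.

    Exactly one of ``dosages`` (integers, MISSING allowed) or ``posteriors``
    (``(n_samples, n_markers, 3)`` simplexes) must drive the GT field; when
    posteriors are given GT is the argmax (``./.`` on ties) and GP carries
    the probabilities. ``emit_gl`` additionally writes
    GL = log10(max(p, 1e-12)).
    """
    import pysam

    if (dosages is None) == (posteriors is None):
        raise ValueError("provide exactly one of dosages or posteriors")

    header = pysam.VariantHeader()
    for chrom in pd.unique(markers["chrom"]):
        header.contigs.add(str(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    if posteriors is not None:
        header.formats.add("GP", "G", "Float", "Genotype probabilities (linear scale)")
        if emit_gl:
            header.formats.add("GL", "G", "Float", "Genotype likelihoods (log10 scale)")
    for s in sample_ids:
        header.add_sample(str(s))

    out = pysam.VariantFile(str(path), "w", header=header)
    for j, marker in enumerate(markers.itertuples(index=False)):
        rec = out.new_record(
            contig=str(marker.chrom),
            start=int(marker.pos) - 1,
            stop=int(marker.pos),
            alleles=(marker.ref, marker.alt),
            id=str(marker.id),
        )
        for i, s in enumerate(sample_ids):
            if posteriors is not None:
                gt, gp = _gt_and_gp(posteriors[i, j])
            else:
                d = int(dosages[i, j])
                gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}[d]
                gp = None
            # GT first: it fixes the ploidy the Number=G fields validate against
            rec.samples[str(s)]["GT"] = gt
            if gp is not None:
                rec.samples[str(s)]["GP"] = gp
                if emit_gl:
                    rec.samples[str(s)]["GL"] = tuple(
                        round(math.log10(max(p, 1e-12)), 6) for p in gp
                    )
            rec.samples[str(s)].phased = phased and gt[0] is not None
        out.write(rec)
    out.close()
    return str(path)


def read_gp(path: str) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a VCF carrying GP, returning the matrix and the simplexes.

    Records without a GP field get a one-hot simplex from GT (uniform for
    missing GT).
    """
    gm = read_vcf(path)
    vcf = VCF(str(path), gts012=True)
    n = len(vcf.samples)
    probs = []
    for rec in vcf:
        try:
            gp = rec.format("GP")
        except KeyError:
            gp = None
        if gp is None:
            gts = np.asarray(rec.gt_types, dtype=np.int16)
            p = np.full((n, 3), 1.0 / 3.0)
            for g in (0, 1, 2):
                p[gts == g] = np.eye(3)[g]
            probs.append(p)
        else:
            probs.append(np.asarray(gp, dtype=float))
    simplexes = (
        np.stack(probs, axis=1) if probs else np.zeros((n, 0, 3))
    )
    sums = simplexes.sum(axis=2)
    if simplexes.size and (np.abs(sums - 1.0) > 1e-4).any():
        raise VcfValidationError("GP fields do not sum to 1")
    simplexes /= sums[..., None]
    return gm, simplexes


def read_genetic_map(path: str) -> GeneticMap:
    """Read a 3-column (chrom, pos, cM) whitespace-delimited map.

    A single header line is tolerated. Within each chromosome positions must
    be strictly increasing and cM non-decreasing.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise MapValidationError("genetic map needs 3 columns: chrom pos cm")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "pos", "cm"]
    # drop an optional header row
    try:
        float(df.iloc[0]["pos"])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.empty:
        raise MapValidationError("genetic map contains no anchors")
    df = df.assign(pos=df["pos"].astype(np.int64), cm=df["cm"].astype(float))
    gmap = GeneticMap()
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cm = sub["cm"].to_numpy()
        dpos = np.diff(pos)
        if (dpos <= 0).any():
            bad = np.flatnonzero(dpos <= 0)[:5]
            raise MapValidationError(
                f"map positions not strictly increasing on {chrom} at rows {bad.tolist()}"
            )
        dcm = np.diff(cm)
        if (dcm < 0).any():
            bad = np.flatnonzero(dcm < 0)[:5]
            raise MapValidationError(
                f"map cM not non-decreasing on {chrom} at rows {bad.tolist()}"
            )
        gmap.anchors[str(chrom)] = (pos, cm)
    return gmap


def interpolate_cm(gmap: GeneticMap, markers: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``cm`` column by linear interpolation between map anchors.

    Markers at anchor positions take the anchor cM; markers between anchors
    are linearly interpolated in physical position; markers outside the
    anchored range are clamped to the boundary cM so genetic distances never
    run negative or extrapolate.
    """
    out = markers.reset_index(drop=True).copy()
    cm = np.empty(len(out), dtype=float)
    for chrom, sub in out.groupby("chrom", sort=False):
        if str(chrom) not in gmap.anchors:
            raise MapValidationError(f"chromosome {chrom} absent from genetic map")
        apos, acm = gmap.anchors[str(chrom)]
        if len(apos) < 2:
            raise MapValidationError(
                f"chromosome {chrom} has fewer than 2 map anchors"
            )
        # np.interp clamps to the boundary values outside the anchor range
        cm[sub.index.to_numpy()] = np.interp(sub["pos"].to_numpy(), apos, acm)
    out["cm"] = cm
    return out
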