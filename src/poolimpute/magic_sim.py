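"""Synthetic MAGIC (multi-parent advanced generation intercross) data
generator.

Produces the statistical structure the pooling-and-imputation pipeline
assumes: 16 fully homozygous founders with a configurable marker MAF
profile, and a population of fully homozygous inbred lines, each a
recombinant mosaic of the founder haplotypes. Every line descends from its
own random funnel — founders paired down over log2(16) = 4 generations of
crossing — followed by several generations of selfing. Meioses place
crossovers as a Poisson process at 1 per Morgan without interference
(Haldane model) on a single chromosome.

Because founders are homozygous, the minimum founder MAF is 1/16; the
descendant lines drift away from the founder spectrum, so rare variants
(MAF < 1/16) appear in the study population exactly as they do in real
multi-parent crosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import MARKER_COLUMNS, GeneticMap, GenotypeMatrix, write_vcf
from .imputation import ReferencePanel

#: founder minor-allele counts whose realized MAF (count/16) falls in each
#: MAF bin [0.05,0.10), [0.10,0.20), [0.20,0.30), [0.30,0.40), [0.40,0.50]
_BIN_COUNTS_16 = [(1,), (2, 3), (4,), (5, 6), (7, 8)]

#: default founder-panel marker proportions per MAF bin (0.05 .. 0.50)
DEFAULT_FOUNDER_MAF_PROFILE = (0.285, 0.343, 0.129, 0.157, 0.086)


class SimulationError(ValueError):
    pass


@dataclass
class MagicSimConfig:
    n_founders: int = 16
    n_lines: int = 496
    n_markers: int = 1170
    chrom_length_cm: float = 150.0
    chrom: str = "1A"
    funnel_generations: int = 4
    selfing_generations: int = 6
    founder_maf_profile: tuple = DEFAULT_FOUNDER_MAF_PROFILE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_founders & (self.n_founders - 1):
            raise SimulationError("n_founders must be a power of 2 for the funnel")
        if abs(sum(self.founder_maf_profile) - 1.0) > 1e-9:
            raise SimulationError("founder_maf_profile must sum to 1")
        if 2**self.funnel_generations != self.n_founders:
            raise SimulationError(
                "funnel_generations must equal log2(n_founders) so the funnel "
                "collapses to a single line"
            )


@dataclass
class TruthSet:
    """Founder panel, inbred-line truth genotypes, genetic map and the
    per-line founder mosaic (which founder each allele was copied from)."""

    founders: ReferencePanel
    lines: GenotypeMatrix
    gmap: GeneticMap
    mosaic: np.ndarray  # (n_lines, n_markers) founder index
    markers: pd.DataFrame = field(default=None)


def _marker_table(config: MagicSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    cm = np.sort(rng.uniform(0.0, config.chrom_length_cm, size=config.n_markers))
    # physical coordinates: monotone in cM with jitter, ~1 Mbp per cM
    gaps = np.diff(np.concatenate([[0.0], cm]))
    bp_gaps = np.maximum((gaps * 1e6 * rng.uniform(0.5, 1.5, size=len(gaps))), 1.0)
    pos = np.cumsum(bp_gaps).astype(np.int64)
    pos = np.maximum.accumulate(pos + np.arange(len(pos)))  # strictly increasing
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=config.n_markers)
    alt = (ref + rng.integers(1, 4, size=config.n_markers)) % 4
    return pd.DataFrame(
        {
            "id": [f"snp{i:05d}" for i in range(config.n_markers)],
            "chrom": config.chrom,
            "pos": pos,
            "ref": bases[ref],
            "alt": bases[alt],
            "cm": cm,
        },
        columns=MARKER_COLUMNS,
    )


def simulate_founders(
    config: MagicSimConfig,
) -> tuple[ReferencePanel, GeneticMap, pd.DataFrame]:
    """Founder haplotype panel plus the genetic map of the marker set.

    Marker cM positions are uniform on [0, chrom_length_cm]. Each marker
    draws a MAF bin from ``founder_maf_profile`` and a compatible founder
    minor-allele count; carriers are uniform among founders, and the minor
    allele is the alternate or the reference with equal probability.
    """
    rng = np.random.default_rng(config.seed)
    markers = _marker_table(config, rng)
    n_bins = len(config.founder_maf_profile)
    bins = rng.choice(n_bins, size=config.n_markers, p=config.founder_maf_profile)
    hap = np.zeros((config.n_founders, config.n_markers), dtype=np.int8)
    bin_edges = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)
    for j, b in enumerate(bins):
        if config.n_founders == 16:
            counts = _BIN_COUNTS_16[b]
            c = int(counts[rng.integers(len(counts))])
        else:
            maf = rng.uniform(bin_edges[b], bin_edges[b + 1])
            c = int(np.clip(round(maf * config.n_founders), 1, config.n_founders // 2))
        carriers = rng.choice(config.n_founders, size=c, replace=False)
        if rng.random() < 0.5:  # minor allele is ALT
            hap[carriers, j] = 1
        else:  # minor allele is REF
            hap[:, j] = 1
            hap[carriers, j] = 0
    panel = ReferencePanel(
        haplotypes=hap,
        labels=[f"founder{i:02d}" for i in range(config.n_founders)],
    )
    gmap = GeneticMap(
        anchors={
            config.chrom: (
                markers["pos"].to_numpy(),
                markers["cm"].to_numpy(),
            )
        }
    )
    return panel, gmap, markers


def _meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cm: np.ndarray,
    length_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a diploid of founder-index haplotypes.

    Crossovers are a Poisson process at 1 per Morgan (Haldane, no
    interference); the gamete copies from one parental haplotype and
    switches at each crossover, starting from a random phase.
    """
    n_xo = rng.poisson(length_cm / 100.0)
    phase0 = rng.integers(2)
    if n_xo == 0:
        return (hap_a if phase0 == 0 else hap_b).copy()
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    phase = (phase0 + np.searchsorted(xo, cm, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_magic_lines(
    panel: ReferencePanel,
    markers: pd.DataFrame,
    config: MagicSimConfig,
) -> TruthSet:
    """Breed ``n_lines`` inbred lines through per-line funnels and selfing.

    Haplotypes are tracked as founder-index mosaics; alleles are read off
    the panel at the end, which makes the mosaic sidecar exact by
    construction. After selfing, any residual heterozygous site is fixed to
    one of its two alleles by a fair coin so the output is fully
    homozygous.
    """
    if panel.n_markers != len(markers):
        raise SimulationError("marker mismatch between panel and marker table")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cm = markers["cm"].to_numpy()
    L = float(config.chrom_length_cm)
    k = panel.k
    n_markers = panel.n_markers

    mosaic = np.empty((config.n_lines, n_markers), dtype=np.int16)
    dosages = np.empty((config.n_lines, n_markers), dtype=np.int16)
    alleles = panel.haplotypes  # (k, M)

    for line in range(config.n_lines):
        founders = rng.permutation(k)
        # founder generation: homozygous diploids (hapA == hapB == founder)
        gen = [
            (np.full(n_markers, f, dtype=np.int16),) * 2 for f in founders
        ]
        # funnel: pair and cross until a single individual remains
        while len(gen) > 1:
            nxt = []
            for a, b in zip(gen[0::2], gen[1::2]):
                g1 = _meiosis(a[0], a[1], cm, L, rng)
                g2 = _meiosis(b[0], b[1], cm, L, rng)
                nxt.append((g1, g2))
            gen = nxt
        ha, hb = gen[0]
        for _ in range(config.selfing_generations):
            ha, hb = (
                _meiosis(ha, hb, cm, L, rng),
                _meiosis(ha, hb, cm, L, rng),
            )
        aa = alleles[ha, np.arange(n_markers)]
        ab = alleles[hb, np.arange(n_markers)]
        het = aa != ab
        pick_b = np.zeros(n_markers, dtype=bool)
        if het.any():
            pick_b[het] = rng.random(int(het.sum())) < 0.5
        src = np.where(pick_b, hb, ha)
        mosaic[line] = src
        dosages[line] = 2 * alleles[src, np.arange(n_markers)]

    lines = GenotypeMatrix(
        sample_ids=[f"line{i:04d}" for i in range(config.n_lines)],
        markers=markers,
        dosages=dosages,
        fully_homozygous=True,
    )
    gmap = GeneticMap(
        anchors={config.chrom: (markers["pos"].to_numpy(), cm)}
    )
    return TruthSet(
        founders=panel, lines=lines, gmap=gmap, mosaic=mosaic, markers=markers
    )


def simulate(config: MagicSimConfig) -> TruthSet:
    """Convenience: founders + lines in one call."""
    panel, _, markers = simulate_founders(config)
    return simulate_magic_lines(panel, markers, config)


def emit_fixture(truth: TruthSet, outdir: str) -> dict[str, str]:
    """Write founders.vcf (phased), truth.vcf, map.txt and mosaic.csv.

    The files round-trip through :mod:`poolimpute.formats_io`; the mosaic
    sidecar records the source founder of every line x marker allele.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    markers = truth.markers
    paths = {
        "founders": str(out / "founders.vcf"),
        "truth": str(out / "truth.vcf"),
        "map": str(out / "map.txt"),
        "mosaic": str(out / "mosaic.csv"),
    }
    write_vcf(
        paths["founders"],
        truth.founders.labels,
        markers,
        dosages=truth.founders.haplotypes * 2,
        phased=True,
    )
    write_vcf(
        paths["truth"],
        truth.lines.sample_ids,
        markers,
        dosages=truth.lines.dosages,
    )
    map_df = pd.DataFrame(
        {
            "chrom": markers["chrom"],
            "pos": markers["pos"],
            "cm": markers["cm"].round(6),
        }
    )
    map_df.to_csv(paths["map"], sep="\t", index=False)
    pd.DataFrame(
        truth.mosaic,
        index=truth.lines.sample_ids,
        columns=markers["id"],
    ).to_csv(paths["mosaic"])
    return paths
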