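"""Synthetic truth sets, reads and standard-format fixtures.

The simulator emulates the statistical structure the downstream analyses
assume: diploid genotypes at biallelic SNP sites drawn under Hardy-Weinberg
equilibrium, per-site read depth that is Poisson around a target mean
coverage, and a per-base sequencing error that flips the observed allele.
Each simulated read covers exactly one variant site, because every analysis
in the toolkit operates on per-site allele counts.

:func:`write_fixture` materialises a truth set and read set as the standard
files a real pipeline would produce - one coordinate-sorted indexed BAM per
sample, a sites-only VCF, a reference FASTA and a truth-genotype TSV - so
the extraction code can be exercised end to end without external data.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Callable

import numpy as np
import pysam

from .types import (
    ALLELE_ALT,
    ALLELE_OTHER,
    ALLELE_REF,
    MultiplexReadSet,
    TruthSet,
    VariantSite,
)

_BASES = np.array(list("ACGT"))

#: Spacing between simulated site positions on the contig (bp).
SITE_SPACING = 100
#: Length of each simulated read (bp); reads are placed so they cover
#: exactly one site (SITE_SPACING > READ_LENGTH guarantees this).
READ_LENGTH = 41
#: 0-based offset of the variant site within each simulated read.
SITE_OFFSET = 20

MafLaw = float | tuple | Callable[[np.random.Generator, int], np.ndarray]


def _draw_mafs(maf_law: MafLaw, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve a MAF specification into per-site alternative-allele frequencies.

    Accepted forms: a float (every site gets that frequency), a tuple
    ``("fixed", p)``, ``("uniform", lo, hi)`` or ``("beta", a, b)``, or a
    callable ``f(rng, n) -> array``.
    """
    if callable(maf_law):
        freqs = np.asarray(maf_law(rng, n_sites), dtype=float)
    elif isinstance(maf_law, (int, float)):
        freqs = np.full(n_sites, float(maf_law))
    elif isinstance(maf_law, tuple):
        kind = maf_law[0]
        if kind == "fixed":
            freqs = np.full(n_sites, float(maf_law[1]))
        elif kind == "uniform":
            freqs = rng.uniform(maf_law[1], maf_law[2], size=n_sites)
        elif kind == "beta":
            freqs = rng.beta(maf_law[1], maf_law[2], size=n_sites)
        else:
            raise ValueError(f"unknown MAF law {kind!r}")
    else:
        raise TypeError(f"cannot interpret MAF law: {maf_law!r}")
    if freqs.shape != (n_sites,):
        raise ValueError("MAF law produced wrong number of frequencies")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return freqs


def simulate_truth(
    n_samples: int,
    n_sites: int,
    maf_law: MafLaw = ("uniform", 0.05, 0.5),
    seed: int = 0,
    contig: str = "chr1",
) -> TruthSet:
    """Simulate diploid truth genotypes at biallelic SNP sites.

    Genotypes at each site are drawn under Hardy-Weinberg equilibrium from
    the site's alternative-allele frequency, i.e. dosage ~ Binomial(2, p)
    independently per sample.  Sites are placed every :data:`SITE_SPACING`
    bp on a single contig with random distinct ref/alt alleles.

    Parameters
    ----------
    n_samples, n_sites
        Dimensions of the truth set; both must be >= 1.
    maf_law
        Per-site alternative-allele frequency specification (see
        :func:`_draw_mafs`).  The default, uniform on [0.05, 0.5], mimics a
        SNP panel ascertained for segregating variants.
    seed
        Seed for the single generator used by this call; recorded on the
        returned :class:`TruthSet` so fixtures are reproducible.
    """
    if n_samples < 1 or n_sites < 1:
        raise ValueError("n_samples and n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = _draw_mafs(maf_law, n_sites, rng)
    genotypes = rng.binomial(2, freqs, size=(n_samples, n_sites)).astype(np.int8)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = [
        VariantSite(contig, SITE_SPACING * (i + 1), _BASES[ref_idx[i]], _BASES[alt_idx[i]])
        for i in range(n_sites)
    ]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return TruthSet(sites=sites, genotypes=genotypes, allele_freqs=freqs,
                    samples=samples, seed=seed)


def simulate_reads(
    truth: TruthSet,
    mean_coverage: float,
    error_rate: float = 0.01,
    seed: int = 0,
) -> MultiplexReadSet:
    """Simulate per-site reads for every sample of a truth set.

    Read depth at each sample-site pair is Poisson(``mean_coverage``),
    matching the depth distribution seen at a base site under random
    sequencing.  Each read transmits one of the two true alleles (each with
    probability dosage/2) and is observed as the transmitted allele with
    probability ``1 - error_rate``, the opposite allele otherwise.  All
    reads start out with MAPQ 60, properly paired, primary and
    non-duplicate; the flags exist so filter behaviour can be tested.
    """
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_samples, n_sites = truth.n_samples, truth.n_sites

    depth = rng.poisson(mean_coverage, size=(n_samples, n_sites))
    total = int(depth.sum())
    flat = depth.ravel()
    pair_idx = np.repeat(np.arange(n_samples * n_sites), flat)
    sample_idx = (pair_idx // n_sites).astype(np.int32)
    site_idx = (pair_idx % n_sites).astype(np.int32)

    dosage = truth.genotypes.ravel()[pair_idx].astype(np.float64)
    transmitted = (rng.random(total) < dosage / 2.0).astype(np.int8)
    flip = rng.random(total) < error_rate
    observed = np.where(flip, 1 - transmitted, transmitted).astype(np.int8)

    return MultiplexReadSet(
        samples=list(truth.samples),
        fragment_id=np.arange(total, dtype=np.int64),
        true_sample=sample_idx,
        assigned_sample=sample_idx.copy(),
        site=site_idx,
        allele=observed,
    )


def tally_counts(
    reads: MultiplexReadSet, n_samples: int, n_sites: int, by_true_sample: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per sample x site (nRef, nAlt) matrices tallied directly from reads.

    Counts are keyed by ``assigned_sample`` (the demultiplexed identity)
    unless ``by_true_sample`` is set.  Reads observed as neither allele
    contribute to neither count.  This tally is the generator-side oracle
    against which BAM extraction is validated.
    """
    sample = reads.true_sample if by_true_sample else reads.assigned_sample
    key = sample.astype(np.int64) * n_sites + reads.site
    minlength = n_samples * n_sites
    nref = np.bincount(key[reads.allele == ALLELE_REF], minlength=minlength)
    nalt = np.bincount(key[reads.allele == ALLELE_ALT], minlength=minlength)
    shape = (n_samples, n_sites)
    return (nref.reshape(shape).astype(np.int32), nalt.reshape(shape).astype(np.int32))


def reference_sequence(truth: TruthSet) -> dict[str, str]:
    """Deterministic reference sequence(s) consistent with the ref alleles.

    Bases are random A/C/G/T seeded from ``truth.seed`` except at site
    positions, which carry the site's reference allele.
    """
    rng = np.random.default_rng(0 if truth.seed is None else truth.seed + 986_131)
    by_contig: dict[str, list[VariantSite]] = {}
    for s in truth.sites:
        by_contig.setdefault(s.contig, []).append(s)
    if not by_contig:
        by_contig["chr1"] = []
    out = {}
    for contig, sites in by_contig.items():
        length = (sites[-1].pos if sites else 0) + SITE_SPACING
        seq = _BASES[rng.integers(0, 4, size=length)]
        for s in sites:
            seq[s.pos - 1] = s.ref
        out[contig] = "".join(seq)
    return out


def _other_base(ref: str, alt: str) -> str:
    for b in "ACGT":
        if b != ref and b != alt:
            return b
    raise AssertionError("unreachable")


def write_fixture(truth: TruthSet, reads: MultiplexReadSet, out_dir: str | os.PathLike) -> dict:
    """Write a truth set and read set as BAM/VCF/FASTA/TSV files.

    Emits one coordinate-sorted, indexed BAM per sample (named after the
    sample), a sites-only VCF v4.2, a reference FASTA (+ .fai) consistent
    with the ref alleles, and a truth-genotype TSV with columns
    ``sample, contig, pos, dosage``.  Returns a dict of the paths written.

    Reads are placed so that each covers exactly its own site; a round trip
    through allele-count extraction therefore recovers the simulated
    per-site tallies exactly when no filters trigger.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    seqs = reference_sequence(truth)

    fasta_path = out / "reference.fa"
    with open(fasta_path, "w") as fh:
        for contig, seq in seqs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    vcf_path = out / "sites.vcf"
    header = pysam.VariantHeader()
    for contig, seq in seqs.items():
        header.contigs.add(contig, length=len(seq))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for s in truth.sites:
            rec = vcf.new_record(contig=s.contig, start=s.pos - 1,
                                 stop=s.pos, alleles=(s.ref, s.alt))
            vcf.write(rec)

    tsv_path = out / "truth.tsv"
    with open(tsv_path, "w") as fh:
        fh.write("sample\tcontig\tpos\tdosage\n")
        for i, sample in enumerate(truth.samples):
            for j, s in enumerate(truth.sites):
                fh.write(f"{sample}\t{s.contig}\t{s.pos}\t{truth.genotypes[i, j]}\n")

    bam_paths = {}
    order = np.lexsort((reads.fragment_id, reads.site, reads.assigned_sample))
    sorted_reads = reads.subset(order)
    bam_header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(seq)} for c, seq in seqs.items()],
    }
    tids = {c: t for t, c in enumerate(seqs)}
    boundaries = np.searchsorted(sorted_reads.assigned_sample, np.arange(truth.n_samples + 1))
    for si, sample in enumerate(truth.samples):
        bam_path = out / f"{sample}.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=bam_header) as bam:
            for k in range(boundaries[si], boundaries[si + 1]):
                j = int(sorted_reads.site[k])
                site = truth.sites[j]
                start0 = site.pos - 1 - SITE_OFFSET
                if start0 < 0:
                    raise ValueError(f"site {site.contig}:{site.pos} too close to contig start")
                seq = list(seqs[site.contig][start0 : start0 + READ_LENGTH])
                code = int(sorted_reads.allele[k])
                if code == ALLELE_REF:
                    seq[SITE_OFFSET] = site.ref
                elif code == ALLELE_ALT:
                    seq[SITE_OFFSET] = site.alt
                elif code == ALLELE_OTHER:
                    seq[SITE_OFFSET] = _other_base(site.ref, site.alt)
                a = pysam.AlignedSegment()
                a.query_name = f"frag{sorted_reads.fragment_id[k]}"
                a.query_sequence = "".join(seq)
                flag = 0x1 | 0x40  # paired, first in pair
                if sorted_reads.proper_pair[k]:
                    flag |= 0x2
                if sorted_reads.secondary[k]:
                    flag |= 0x100
                if sorted_reads.duplicate[k]:
                    flag |= 0x400
                a.flag = flag
                a.reference_id = tids[site.contig]
                a.reference_start = start0
                a.mapping_quality = int(sorted_reads.mapq[k])
                a.cigartuples = [(0, READ_LENGTH)]
                a.next_reference_id = tids[site.contig]
                a.next_reference_start = start0
                a.template_length = 0
                a.query_qualities = pysam.qualitystring_to_array("I" * READ_LENGTH)
                bam.write(a)
        pysam.index(str(bam_path))
        bam_paths[sample] = str(bam_path)

    return {
        "fasta": str(fasta_path),
        "vcf": str(vcf_path),
        "truth_tsv": str(tsv_path),
        "bams": bam_paths,
    }
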