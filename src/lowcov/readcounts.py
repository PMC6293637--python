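"""Allele read-count extraction from alignments.

Low-coverage genotype calling is unbiased only if the per-allele read
counts come straight from the aligned reads, not from a variant caller's
per-site summaries (whose local-assembly pruning re-attributes weakly
supported alternative alleles to the reference).  This module extracts
``(nRef, nAlt)`` for a list of biallelic SNP sites directly from a BAM
file, applying the standard read filters: minimum mapping quality, proper
pairing, and exclusion of secondary and duplicate alignments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import FilterConfig, VariantSite


def read_sites_vcf(path: str | os.PathLike) -> list[VariantSite]:
    """Load biallelic SNP sites from a VCF (only CHROM/POS/REF/ALT are used).

    Records that are not biallelic SNPs are rejected with an error naming
    the offending coordinate.
    """
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"site {rec.chrom}:{rec.pos} is not biallelic")
            try:
                sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            except ValueError as exc:
                raise ValueError(f"malformed site in {path}: {exc}") from exc
    return sites


def _site_base(read: pysam.AlignedSegment, pos0: int) -> tuple[str | None, int | None]:
    """Base (and base quality) this read shows at reference position ``pos0``.

    Returns ``(None, None)`` when the position falls in a deletion, an
    intron/clip, or outside the aligned portion of the read - such reads
    contribute no observation at the site.
    """
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            base = read.query_sequence[qpos]
            qual = read.query_qualities[qpos] if read.query_qualities is not None else None
            return base, qual
    return None, None


def extract_allele_counts(
    alignment_file: str | os.PathLike,
    sites: Sequence[VariantSite],
    filters: FilterConfig = FilterConfig(),
    count_fragments: bool = False,
) -> pd.DataFrame:
    """Extract (nRef, nAlt) for every site from a coordinate-sorted BAM.

    For each site, ``nRef`` counts passing reads whose aligned base at the
    site equals the reference allele and ``nAlt`` likewise for the
    alternative allele; reads showing any other base, an N, or a deletion
    at the site are ignored.  Each read contributes at most one observation
    per site.  When both mates of a pair overlap the site they are both
    counted unless ``count_fragments`` is set, in which case only the first
    encountered mate of each fragment counts.

    Returns a DataFrame with one row per site, in input order, with columns
    ``contig, pos, ref, alt, nRef, nAlt``.

    Raises
    ------
    FileNotFoundError
        If the BAM index is missing.
    ValueError
        If a site's contig is absent from the BAM header.
    """
    path = str(alignment_file)
    with pysam.AlignmentFile(path) as bam:
        try:
            has_index = bam.check_index()
        except (ValueError, AttributeError):
            has_index = False
        if not has_index:
            raise FileNotFoundError(
                f"alignment file {path} has no index (.bai); sort and index it first"
            )
        known = set(bam.references)
        rows = []
        for site in sites:
            if site.contig not in known:
                raise ValueError(
                    f"contig {site.contig!r} absent from BAM header of {path}"
                )
            pos0 = site.pos - 1
            nref = nalt = 0
            seen_fragments: set[str] = set()
            for read in bam.fetch(site.contig, pos0, pos0 + 1):
                if read.is_unmapped or read.is_qcfail:
                    continue
                if filters.drop_secondary and read.is_secondary:
                    continue
                if read.is_supplementary:
                    continue
                if filters.drop_duplicates and read.is_duplicate:
                    continue
                if read.mapping_quality < filters.min_mapq:
                    continue
                if filters.require_proper_pair and not read.is_proper_pair:
                    continue
                base, qual = _site_base(read, pos0)
                if base is None:
                    continue
                if qual is not None and qual < filters.min_baseq:
                    continue
                if count_fragments:
                    if read.query_name in seen_fragments:
                        continue
                    seen_fragments.add(read.query_name)
                if base == site.ref:
                    nref += 1
                elif base == site.alt:
                    nalt += 1
            rows.append((site.contig, site.pos, site.ref, site.alt, nref, nalt))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "nRef", "nAlt"])


def extract_allele_counts_multi(
    bams: Mapping[str, str | os.PathLike],
    sites: Sequence[VariantSite],
    filters: FilterConfig = FilterConfig(),
    count_fragments: bool = False,
) -> pd.DataFrame:
    """Extract counts for several samples; adds a leading ``sample`` column."""
    frames = []
    for sample, path in bams.items():
        df = extract_allele_counts(path, sites, filters, count_fragments)
        df.insert(0, "sample", sample)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Coverage strata


@dataclass(frozen=True)
class CoverageBins:
    """Partition of positive depths into labelled strata.

    ``bins`` maps a label to an inclusive ``(lo, hi)`` depth range.  Depths
    outside every bin (including depth 0) map to :data:`EXCLUDED`.
    """

    bins: tuple[tuple[str, int, int], ...]

    EXCLUDED = "excluded"

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for label, lo, hi in self.bins:
            if lo < 1 or hi < lo:
                raise ValueError(f"stratum {label!r}: invalid range [{lo}, {hi}]")
            span = set(range(lo, hi + 1))
            if covered & span:
                raise ValueError(f"stratum {label!r} overlaps another stratum")
            covered |= span

    def label(self, depth: int) -> str:
        if depth >= 1:
            for lab, lo, hi in self.bins:
                if lo <= depth <= hi:
                    return lab
        return self.EXCLUDED

    def labels(self, depths: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`label`."""
        depths = np.asarray(depths)
        out = np.full(depths.shape, self.EXCLUDED, dtype=object)
        for lab, lo, hi in self.bins:
            out[(depths >= lo) & (depths <= hi)] = lab
        return out

    @property
    def ordered_labels(self) -> list[str]:
        return [lab for lab, _, _ in self.bins]


#: Default strata used by the coverage-stratified concordance tables:
#: single depths 1-5 and a pooled 6-10 bin; anything deeper is excluded.
DEFAULT_BINS = CoverageBins(
    (
        ("1x", 1, 1),
        ("2x", 2, 2),
        ("3x", 3, 3),
        ("4x", 4, 4),
        ("5x", 5, 5),
        ("6-10x", 6, 10),
    )
)


def coverage_stratum(nref: int, nalt: int, bins: CoverageBins = DEFAULT_BINS) -> str:
    """Stratum label for a site's depth ``nRef + nAlt`` (or ``"excluded"``)."""
    return bins.label(int(nref) + int(nalt))


# ---------------------------------------------------------------------------
# Counts TSV dialect

COUNT_COLUMNS = ["sample", "contig", "pos", "ref", "alt", "nRef", "nAlt"]


def write_counts_tsv(df: pd.DataFrame, path: str | os.PathLike,
                     header_lines: Iterable[str] = ()) -> None:
    """Write a counts table in the toolkit's TSV dialect.

    ``header_lines`` are emitted as leading ``#``-prefixed comment lines
    (used e.g. to record allele orientation for tailored-reference counts).
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("contig", "pos", "nRef", "nAlt") if c not in df.columns]
    if missing:
        raise ValueError(f"counts file {path} lacks required columns: {missing}")
    return df
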