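"""Shared domain types.

The toolkit operates on biallelic SNP sites, per-sample allele read counts
at those sites, and multiplexed read sets in which each read remembers both
the sample it truly came from and the sample it is currently assigned to
(the two differ after index hopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = frozenset("ACGT")

#: Dosage code used for "no call" throughout the toolkit.
NO_CALL: int = -1

#: Observed-allele codes carried by simulated reads.
ALLELE_REF, ALLELE_ALT, ALLELE_OTHER = 0, 1, 2


@dataclass(frozen=True, slots=True)
class VariantSite:
    """A biallelic SNP: 1-based position plus reference and alternative allele."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site {self.contig}:{self.pos}: position must be >= 1")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"site {self.contig}:{self.pos}: alleles must be single bases in "
                f"A/C/G/T, got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(
                f"site {self.contig}:{self.pos}: ref and alt alleles are identical"
            )


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Read filters applied when extracting allele counts from alignments.

    Defaults mirror common practice for pileup-based genotyping of
    short-read data: discard reads below MAPQ 20, reads not aligned in a
    proper pair, secondary alignments and duplicate-marked reads.  No
    base-quality filter is applied by default.
    """

    min_mapq: int = 20
    require_proper_pair: bool = True
    drop_secondary: bool = True
    drop_duplicates: bool = True
    min_baseq: int = 0

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.min_baseq < 0:
            raise ValueError("min_baseq must be >= 0")


@dataclass
class TruthSet:
    """Simulated ground truth: sites, per-sample dosages and allele frequencies.

    ``genotypes`` is a samples x sites matrix of alternative-allele dosages
    in {0, 1, 2}.  Site positions are strictly increasing within a contig.
    """

    sites: list[VariantSite]
    genotypes: np.ndarray
    allele_freqs: np.ndarray
    samples: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        n_samples, n_sites = self.genotypes.shape
        if n_sites != len(self.sites):
            raise ValueError("genotype matrix width does not match number of sites")
        if n_samples != len(self.samples):
            raise ValueError("genotype matrix height does not match number of samples")
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.contig in last and s.pos <= last[s.contig]:
                raise ValueError(
                    f"site positions must be strictly increasing on {s.contig} "
                    f"(offending position {s.pos})"
                )
            last[s.contig] = s.pos

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class MultiplexReadSet:
    """Reads of several samples sharing a lane, stored column-wise.

    Each record is one sequenced fragment observed at exactly one variant
    site.  ``true_sample`` is the sample of origin; ``assigned_sample`` is
    the sample the fragment is demultiplexed to (equal to ``true_sample``
    until index hopping is injected).  ``allele`` uses the codes
    :data:`ALLELE_REF`, :data:`ALLELE_ALT`, :data:`ALLELE_OTHER`.
    """

    samples: list[str]
    fragment_id: np.ndarray
    true_sample: np.ndarray
    assigned_sample: np.ndarray
    site: np.ndarray
    allele: np.ndarray
    mapq: np.ndarray = field(default=None)  # type: ignore[assignment]
    proper_pair: np.ndarray = field(default=None)  # type: ignore[assignment]
    secondary: np.ndarray = field(default=None)  # type: ignore[assignment]
    duplicate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.fragment_id)
        self.fragment_id = np.asarray(self.fragment_id, dtype=np.int64)
        self.true_sample = np.asarray(self.true_sample, dtype=np.int32)
        self.assigned_sample = np.asarray(self.assigned_sample, dtype=np.int32)
        self.site = np.asarray(self.site, dtype=np.int32)
        self.allele = np.asarray(self.allele, dtype=np.int8)
        if self.mapq is None:
            self.mapq = np.full(n, 60, dtype=np.uint8)
        if self.proper_pair is None:
            self.proper_pair = np.ones(n, dtype=bool)
        if self.secondary is None:
            self.secondary = np.zeros(n, dtype=bool)
        if self.duplicate is None:
            self.duplicate = np.zeros(n, dtype=bool)
        for name in ("true_sample", "assigned_sample", "site", "allele",
                     "mapq", "proper_pair", "secondary", "duplicate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has inconsistent length")

    def __len__(self) -> int:
        return len(self.fragment_id)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, index: np.ndarray) -> "MultiplexReadSet":
        """Return a new read set restricted to a boolean mask or index array."""
        return MultiplexReadSet(
            samples=self.samples,
            fragment_id=self.fragment_id[index],
            true_sample=self.true_sample[index],
            assigned_sample=self.assigned_sample[index],
            site=self.site[index],
            allele=self.allele[index],
            mapq=self.mapq[index],
            proper_pair=self.proper_pair[index],
            secondary=self.secondary[index],
            duplicate=self.duplicate[index],
        )

    def copy(self) -> "MultiplexReadSet":
        # note: an explicit deep copy — slice-based subsetting would alias
        # the underlying arrays and let in-place edits leak back
        return MultiplexReadSet(
            samples=list(self.samples),
            fragment_id=self.fragment_id.copy(),
            true_sample=self.true_sample.copy(),
            assigned_sample=self.assigned_sample.copy(),
            site=self.site.copy(),
            allele=self.allele.copy(),
            mapq=self.mapq.copy(),
            proper_pair=self.proper_pair.copy(),
            secondary=self.secondary.copy(),
            duplicate=self.duplicate.copy(),
        )

    def to_frame(self):
        """Long-format pandas view (one row per fragment)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "fragment_id": self.fragment_id,
                "true_sample": np.asarray(self.samples)[self.true_sample],
                "assigned_sample": np.asarray(self.samples)[self.assigned_sample],
                "site": self.site,
                "allele": self.allele,
                "mapq": self.mapq,
                "proper_pair": self.proper_pair,
                "secondary": self.secondary,
                "duplicate": self.duplicate,
            }
        )
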