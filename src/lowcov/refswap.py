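"""Tailored-reference construction and dual-alignment count combination.

Read alignment against a haploid reference genome slightly favours reads
carrying the allele that is present in the reference.  To measure this
bias, reads are aligned twice: against the original reference and against
a "tailored" reference in which the alternative allele has been substituted
at every known SNP site.  Counts from the two alignments can then be
combined so that each allele gets its most favourable alignment (CIS) or
its least favourable one (TRANS), alongside the plain REF and ALT cases.

Allele orientation convention: all count tables handled here are expressed
in *original*-reference orientation - ``nRef`` always counts the allele
that is the reference allele of the original genome, even for counts
extracted against the tailored genome (where that allele is the one
substituted out).  Re-express tailored-alignment counts before combining.
"""

from __future__ import annotations

import os
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .types import VariantSite

MODES = ("REF", "ALT", "CIS", "TRANS")

#: Header line written into count TSVs to make the orientation explicit.
ORIENTATION_HEADER = "orientation: original-reference (nRef counts the original reference allele)"


def build_tailored_reference(
    genome: str | os.PathLike,
    sites: Sequence[VariantSite],
    out: str | os.PathLike,
    line_width: int = 60,
) -> str:
    """Write a copy of ``genome`` with the alt allele substituted at each site.

    The output FASTA is identical to the input except that every site
    position carries the site's alternative allele; sequence lengths are
    unchanged (SNPs only).  Every site's declared reference allele is
    validated against the genome base; mismatches and duplicate site
    positions are rejected.  The output is faidx-indexed.  Applying the
    operation twice with ref/alt swapped restores the original sequence.
    """
    by_contig: dict[str, list[VariantSite]] = defaultdict(list)
    seen: set[tuple[str, int]] = set()
    for s in sites:
        key = (s.contig, s.pos)
        if key in seen:
            raise ValueError(f"duplicate site at {s.contig}:{s.pos}")
        seen.add(key)
        by_contig[s.contig].append(s)

    fasta = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    try:
        contigs = list(fasta.keys())
        for contig in by_contig:
            if contig not in fasta:
                raise ValueError(f"contig {contig!r} not present in {genome}")
        mismatches = [
            f"{s.contig}:{s.pos} (genome={fasta[s.contig][s.pos - 1]}, declared ref={s.ref})"
            for ss in by_contig.values()
            for s in ss
            if fasta[s.contig][s.pos - 1] != s.ref
        ]
        if mismatches:
            raise ValueError(
                "genome base differs from declared reference allele at: "
                + ", ".join(mismatches)
            )
        with open(out, "w") as fh:
            for contig in contigs:
                seq = np.array(list(fasta[contig][:]))
                for s in by_contig.get(contig, []):
                    seq[s.pos - 1] = s.alt
                fh.write(f">{contig}\n")
                text = "".join(seq)
                for i in range(0, len(text), line_width):
                    fh.write(text[i : i + line_width] + "\n")
    finally:
        fasta.close()
    Fasta(str(out)).close()  # build the .fai index
    return str(out)


def _merge_keyed(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    keys = [c for c in ("sample", "contig", "pos") if c in a.columns and c in b.columns]
    if not ("contig" in keys and "pos" in keys):
        raise ValueError("count tables must share at least 'contig' and 'pos' columns")
    ka = a.set_index(keys).index
    kb = b.set_index(keys).index
    if len(ka) != len(kb) or set(ka) != set(kb):
        offending = next(iter(set(ka) ^ set(kb)))
        raise ValueError(f"count tables are not keyed identically; first mismatch: {offending}")
    merged = a.merge(b, on=keys, suffixes=("_refaln", "_altaln"), validate="one_to_one")
    return merged, keys


def combine_counts(
    counts_ref_aln: pd.DataFrame,
    counts_alt_aln: pd.DataFrame,
    mode: str,
) -> pd.DataFrame:
    """Combine original- and tailored-alignment counts in one of four modes.

    Both inputs use the readcounts TSV dialect in original-reference
    orientation.  REF and ALT return the respective table unchanged; CIS
    takes nRef from the original alignment and nAlt from the tailored one
    (each allele's favourable alignment); TRANS the other way round.
    """
    mode = mode.upper()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "REF":
        return counts_ref_aln.copy()
    if mode == "ALT":
        return counts_alt_aln.copy()
    merged, keys = _merge_keyed(counts_ref_aln, counts_alt_aln)
    out = merged[keys].copy()
    for col in ("ref", "alt"):
        if f"{col}_refaln" in merged.columns:
            out[col] = merged[f"{col}_refaln"]
    if mode == "CIS":
        out["nRef"] = merged["nRef_refaln"]
        out["nAlt"] = merged["nAlt_altaln"]
    else:  # TRANS
        out["nRef"] = merged["nRef_altaln"]
        out["nAlt"] = merged["nAlt_refaln"]
    return out


def alignment_bias_summary(
    counts_ref_aln: pd.DataFrame,
    counts_alt_aln: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean per-site allele counts under each genome, and the loss percentages.

    For each allele the favourable genome is the one carrying that allele
    (original for the reference allele, tailored for the alternative);
    reads of an allele that fail to align when the genome carries the
    opposite allele show up as the relative difference

        100 * (mean_favourable - mean_unfavourable) / mean_favourable.

    Returns one row per allele with the two means and the difference,
    overall and - when a ``truth`` table with columns ``sample, contig,
    pos, dosage`` is supplied - stratified by true genotype.
    """
    merged, keys = _merge_keyed(counts_ref_aln, counts_alt_aln)
    if merged.empty:
        raise ValueError("count tables have an empty intersection")
    if truth is not None:
        tkeys = [k for k in keys if k in truth.columns]
        merged = merged.merge(
            truth[tkeys + ["dosage"]].rename(columns={"dosage": "true"}),
            on=tkeys, how="inner", validate="one_to_one",
        )
        if merged.empty:
            raise ValueError("truth table shares no keys with the count tables")

    strata: list[tuple[str, pd.DataFrame]] = [("overall", merged)]
    if truth is not None:
        strata += [(f"true={g}", merged[merged["true"] == g]) for g in (0, 1, 2)]

    rows = []
    spec = [
        ("reference", "nRef_refaln", "nRef_altaln"),  # favourable genome: original
        ("alternative", "nAlt_altaln", "nAlt_refaln"),  # favourable genome: tailored
    ]
    for allele, fav_col, unfav_col in spec:
        for label, sub in strata:
            fav = float(sub[fav_col].mean()) if len(sub) else float("nan")
            unfav = float(sub[unfav_col].mean()) if len(sub) else float("nan")
            diff = 100.0 * (fav - unfav) / fav if fav else float("nan")
            rows.append((allele, label, len(sub), fav, unfav, diff))
    return pd.DataFrame(
        rows,
        columns=[
            "allele", "stratum", "n_sites",
            "mean_favourable", "mean_unfavourable", "difference_percent",
        ],
    )
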