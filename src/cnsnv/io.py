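"""Readers and writers for allelic counts, copy-number segments and calls.

All coordinates are 1-based and segment intervals are inclusive on both
ends, matching the coordinate style of the segment tables the model was
designed to consume (e.g. a chr19 high-level amplicon spanning
24301089-63793263 contains both endpoints).
"""
from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .model import CNAState

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref_count", "depth"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "state_code"]
CALL_COLUMNS = [
    "chrom", "pos", "ref_count", "depth", "state_code",
    "map_genotype", "p_snv", "passed", "posterior",
]

#: phred cap applied to VCF QUAL when p(SNV) is numerically 1
QUAL_CAP = 255.0


def read_counts(path) -> pd.DataFrame:
    """Read a tab-separated allelic-count file (chrom, pos, ref_count, depth).

    A header line is auto-detected (non-numeric position field).  Records
    violating 0 <= ref_count <= depth and otherwise malformed lines are
    rejected and logged with their line number; extra columns are ignored.
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                logger.error("%s:%d: expected >= 4 tab-separated fields", path, lineno)
                n_bad += 1
                continue
            try:
                pos, a, n = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                logger.error("%s:%d: non-integer pos/ref_count/depth", path, lineno)
                n_bad += 1
                continue
            if pos < 1:
                logger.error("%s:%d: position %d < 1", path, lineno, pos)
                n_bad += 1
                continue
            if not (0 <= a <= n):
                logger.error(
                    "%s:%d: violates 0 <= ref_count <= depth (ref_count=%d, depth=%d)",
                    path, lineno, a, n,
                )
                n_bad += 1
                continue
            rows.append((parts[0], pos, a, n))
    if n_bad and not rows:
        raise ValueError(f"no parseable count records in {path} ({n_bad} bad line(s))")
    if not rows:
        logger.warning("count file %s is empty", path)
    return pd.DataFrame(rows, columns=COUNT_COLUMNS).astype(
        {"chrom": str, "pos": np.int64, "ref_count": np.int64, "depth": np.int64}
    )


def read_segments(path) -> pd.DataFrame:
    """Read and validate a copy-number segment file.

    Tab-separated chrom, start, end, state_code with codes 2 (NEUT/LOSS),
    3 (GAIN), 4 (AMP), 5 (HLAMP).  Segments are sorted per chromosome and
    must not overlap (abutting 1-based inclusive intervals are fine).
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-integer start/end") from None
            state = CNAState.from_code(parts[3])
            if start > end:
                raise ValueError(
                    f"{path}:{lineno}: segment start {start} > end {end}"
                )
            rows.append((parts[0], start, end, int(state)))
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS).astype(
        {"chrom": str, "start": np.int64, "end": np.int64, "state_code": np.int64}
    )
    seg = seg.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, sub in seg.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bad = np.nonzero(starts[1:] <= ends[:-1])[0]
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"overlapping segments on chromosome {chrom}: "
                f"[{starts[i]}, {ends[i]}] and [{starts[i + 1]}, {ends[i + 1]}]"
            )
    return seg


def annotate_states(
    counts: pd.DataFrame,
    segments: Optional[pd.DataFrame],
    default_state: CNAState = CNAState.NEUT_LOSS,
) -> pd.DataFrame:
    """Attach a copy-number state to every position.

    Each position takes the state of the unique segment containing it
    (1-based inclusive on both ends, binary search over the sorted
    per-chromosome segments); positions in no segment get ``default_state``.
    """
    out = counts.copy()
    out["state_code"] = int(default_state)
    if segments is None or len(segments) == 0:
        return out
    for chrom, sub in segments.groupby("chrom"):
        mask = out["chrom"] == chrom
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        codes = sub["state_code"].to_numpy()
        pos = out.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.maximum(idx, 0)])
        assigned = np.full(pos.shape, int(default_state), dtype=np.int64)
        assigned[inside] = codes[idx[inside]]
        out.loc[mask, "state_code"] = assigned
    return out


def _format_posterior(vec) -> str:
    return ",".join(f"{x:.17g}" for x in np.asarray(vec, float))


def _parse_posterior(text: str) -> np.ndarray:
    # python's float() is correctly rounded, so the %.17g round-trip is exact
    return np.array([float(x) for x in str(text).split(",")])


def write_calls(calls: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a call table as TSV (round-trippable) or minimal VCF 4.2."""
    if format == "tsv":
        _write_calls_tsv(calls, path)
    elif format == "vcf":
        _write_calls_vcf(calls, path)
    else:
        raise ValueError(f"unknown output format {format!r} (expected 'tsv' or 'vcf')")


def _write_calls_tsv(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.ref_count}\t{row.depth}\t"
                f"{row.state_code}\t{row.map_genotype}\t{row.p_snv:.17g}\t"
                f"{int(bool(row.passed))}\t{_format_posterior(row.posterior)}\n"
            )


def read_calls(path) -> pd.DataFrame:
    """Read back a TSV call table written by :func:`write_calls`."""
    df = pd.read_csv(
        path,
        sep="\t",
        float_precision="round_trip",
        dtype={
            "chrom": str, "pos": np.int64, "ref_count": np.int64,
            "depth": np.int64, "state_code": np.int64,
            "map_genotype": str, "p_snv": float, "passed": np.int64,
            "posterior": str,
        },
    )
    df["passed"] = df["passed"].astype(bool)
    df["posterior"] = df["posterior"].map(_parse_posterior)
    return df


def phred_qual(p: float, cap: float = QUAL_CAP) -> float:
    """Phred-scaled call quality -10*log10(1 - p(SNV)), capped."""
    err = 1.0 - p
    if err <= 0:
        return cap
    return min(-10.0 * math.log10(err), cap)


def _write_calls_vcf(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cnsnv\n")
        fh.write(
            '##INFO=<ID=CN,Number=1,Type=Integer,'
            'Description="Copy-number state code (2=NEUT/LOSS,3=GAIN,4=AMP,5=HLAMP)">\n'
        )
        fh.write('##INFO=<ID=MAPGT,Number=1,Type=String,Description="MAP genotype">\n')
        fh.write(
            '##INFO=<ID=PSNV,Number=1,Type=Float,'
            'Description="Posterior probability the position carries a variant genotype">\n'
        )
        fh.write('##FILTER=<ID=lowPSNV,Description="p(SNV) below the call threshold">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            qual = phred_qual(float(row.p_snv))
            filt = "PASS" if bool(row.passed) else "lowPSNV"
            info = f"CN={row.state_code};MAPGT={row.map_genotype};PSNV={row.p_snv:.6g}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\tN\t.\t{qual:.2f}\t{filt}\t{info}\n"
            )


def counts_from_bam(
    bam_path,
    positions: pd.DataFrame,
    fasta_path=None,
    min_mapq: int = 10,
    min_baseq: int = 20,
) -> pd.DataFrame:
    """Optional convenience: extract allelic counts from an alignment file.

    ``positions`` needs columns chrom, pos, ref_base.  Reads below the
    mapping/base-quality cutoffs are ignored.  Accepts SAM or BAM.
    """
    import pysam

    mode = "r" if str(bam_path).endswith(".sam") else "rb"
    rows = []
    with pysam.AlignmentFile(str(bam_path), mode, reference_filename=(
        str(fasta_path) if fasta_path else None
    )) as af:
        for row in positions.itertuples(index=False):
            ref = str(row.ref_base).upper()
            a = n = 0
            for col in af.pileup(
                str(row.chrom), row.pos - 1, row.pos,
                truncate=True, min_mapping_quality=min_mapq,
                min_base_quality=min_baseq, ignore_overlaps=False,
            ):
                if col.reference_pos != row.pos - 1:
                    continue
                for read in col.pileups:
                    if read.is_del or read.is_refskip or read.query_position is None:
                        continue
                    base = read.alignment.query_sequence[read.query_position].upper()
                    n += 1
                    if base == ref:
                        a += 1
            rows.append((str(row.chrom), int(row.pos), a, n))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
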