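"""File formats: SAM/BAM alignments, FASTA/FASTQ sequences, cohort TSV.

TSV is the canonical tabular dialect (tab-separated, header row, UTF-8,
'.' decimal); every table starts with '#'-prefixed provenance lines
(version, seed, config hash) that readers skip.  SAM is the required
alignment interface; BAM works through the same pysam reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .caller import Genotype, LocusRead
from .locus import RepeatLocus

logger = logging.getLogger(__name__)

__all__ = [
    "provenance_lines",
    "read_alignments",
    "write_sam",
    "write_fastq",
    "write_fasta",
    "load_cohort",
    "write_cohort",
    "write_genotypes",
    "load_genotypes",
]


def provenance_lines(seed=None, config_hash: str | None = None) -> list[str]:
    parts = [f"qtronset {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return ["# " + " ".join(parts)]


def config_digest(obj) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# ----------------------------------------------------------------------
# alignments
# ----------------------------------------------------------------------

def _window_contig(locus: RepeatLocus) -> tuple[str, int, int]:
    """Contig name and the genomic start (0-based) of the locus window."""
    start0 = locus.start - 1 - len(locus.left_flank)
    return locus.chromosome, start0, start0 + len(locus.reference_window())


def read_alignments(
    paths,
    locus: RepeatLocus,
    margin: int = 0,
    sample: str = "",
) -> list[LocusRead]:
    """Reads overlapping the locus window from one or more SAM/BAM files.

    Multiple files for the same sample are merged (multiple sequencing
    runs of one individual).  Malformed/unmapped records are skipped
    with a logged count.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    contig, win_start, win_end = _window_contig(locus)
    lo, hi = win_start - margin, win_end + margin
    out: list[LocusRead] = []
    for path in paths:
        path = str(path)
        mode = "rb" if path.endswith(".bam") else "r"
        skipped = 0
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for rec in fh:
                try:
                    if rec.is_unmapped or rec.query_sequence is None:
                        skipped += 1
                        continue
                    ref_name = rec.reference_name
                    if ref_name not in (contig, "locus_window"):
                        continue
                    start = rec.reference_start
                    end = rec.reference_end or (start + rec.query_length)
                    if ref_name == contig and (end <= lo or start >= hi):
                        continue
                    mate = 2 if rec.is_read2 else 1
                    pos = start - (win_start if ref_name == contig else 0)
                    out.append(
                        LocusRead(
                            rec.query_name, rec.query_sequence, mate,
                            sample, pos,
                        )
                    )
                except (ValueError, KeyError):
                    skipped += 1
        if skipped:
            logger.info("%s: skipped %d unusable records", path, skipped)
    return out


def write_sam(
    reads: list[LocusRead], locus: RepeatLocus, path, use_genomic: bool = True
) -> None:
    """Write locus reads as a SAM file.

    Positions are the simulator's placement hints lifted to genomic
    coordinates (or to a ``locus_window`` contig when ``use_genomic`` is
    false); the caller realigns, so the CIGAR is plain match.
    """
    contig, win_start, _ = _window_contig(locus)
    if use_genomic:
        ref_name, offset, ref_len = contig, win_start, win_start + 10_000_000
    else:
        ref_name, offset, ref_len = (
            "locus_window", 0, len(locus.reference_window())
        )
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
        "PG": [{"ID": "qtronset", "PN": "qtronset", "VN": __version__}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.name
            a.query_sequence = read.seq
            a.flag = (0x1 | 0x40) if read.mate == 1 else (0x1 | 0x80 | 0x10)
            a.reference_id = 0
            a.reference_start = max(read.pos, 0) + offset
            a.mapping_quality = 60
            a.cigartuples = [(0, len(read.seq))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            fh.write(a)


_COMP = str.maketrans("ACGTN", "TGCAN")


def write_fastq(reads: list[LocusRead], path1, path2=None) -> None:
    """FASTQ export; mate-2 sequences are reverse-complemented."""
    f1 = open(path1, "w")
    f2 = open(path2, "w") if path2 else f1
    try:
        for read in reads:
            seq = read.seq
            if read.mate == 2:
                seq = seq.translate(_COMP)[::-1]
            fh = f1 if read.mate == 1 else f2
            fh.write(f"@{read.name}/{read.mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    finally:
        f1.close()
        if path2:
            f2.close()


def write_fasta(records: dict[str, str], path) -> None:
    """Write named sequences (e.g. allele haplotypes) as FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path), "fasta",
    )


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_cohort(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    _write_table(df, path, provenance_lines(seed, config_hash))


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "selected" in df.columns:
        df["selected"] = df["selected"].astype(bool)
    return df


def write_genotypes(
    genotypes: dict[str, Genotype | None], path, seed=None, config_hash=None
) -> None:
    rows = []
    for sample, g in sorted(genotypes.items()):
        if g is None:
            rows.append(
                {"sample": sample, "qtr_a": "", "qtr_b": "", "str_a": "",
                 "str_b": "", "depth": 0, "zygosity": "uncallable",
                 "matched_a": "", "matched_b": "", "qc": "low-depth"}
            )
            continue
        rows.append(
            {
                "sample": sample,
                "qtr_a": g.allele_a.qtr_units,
                "qtr_b": g.allele_b.qtr_units,
                "str_a": g.allele_a.str_units,
                "str_b": g.allele_b.str_units,
                "depth": g.depth,
                "zygosity": g.zygosity,
                "matched_a": g.allele_a.matched_spec or "",
                "matched_b": g.allele_b.matched_spec or "",
                "qc": ";".join(g.qc_flags),
            }
        )
    _write_table(pd.DataFrame(rows), path, provenance_lines(seed, config_hash))


def load_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
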