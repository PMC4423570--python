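"""Readers and writers for caller-output dialects and prediction reports.

Supported inputs: amplicon/copy-number-gain calls as BED (with an optional
coverage column), SV breakpoint calls in BreakDancer native tab format,
Delly-style VCF (SVTYPE/END/CHR2 INFO keys, read through cyvcf2) and generic
BEDPE, plus a samtools-depth-like per-base depth table.  Outputs: a
prediction TSV, a junction BEDPE, and a GraphViz DOT rendering, all
byte-deterministic for identical input.

Coordinate conventions: BED and BEDPE are 0-based half-open and pass through
unchanged; BreakDancer and VCF positions are 1-based and are shifted by -1 on
read.  Internally everything is 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .records import Amplicon, Breakend, DMPrediction, RawCnvCall, SVCall

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files; carries file path and line number."""

    def __init__(self, path, lineno: Optional[int], message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


def _int_field(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {value!r}") from None


# ---------------------------------------------------------------------------
# Amplicon / CNV input
# ---------------------------------------------------------------------------

def read_amplicon_bed(path) -> List[RawCnvCall]:
    """Read amplified-copy-number calls from a BED file.

    Columns: chrom, start, end, name[, coverage].  The 5th column, when
    present, is the mean mapping coverage; without it the record's coverage
    is ``None`` and the coverage-uniformity filter cannot run unless a depth
    table fills it in later.
    """
    calls: List[RawCnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >=4 columns, got {len(fields)}")
            chrom = fields[0]
            start = _int_field(fields[1], path, lineno, "start")
            end = _int_field(fields[2], path, lineno, "end")
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            coverage = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    coverage = float(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric coverage: {fields[4]!r}") from None
            calls.append(RawCnvCall(chrom, start, end, coverage))
    return calls


def compute_amplicon_coverage(depth_path, amplicons: Sequence[RawCnvCall]) -> List[RawCnvCall]:
    """Fill amplicon coverages from a samtools-depth-like table.

    The table is TSV ``chrom, pos (1-based), depth``.  Coverage of an
    amplicon is the sum of depths at its positions divided by its length;
    positions absent from the table count as depth 0.
    """
    depth = pd.read_csv(
        depth_path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": int, "depth": float},
    )
    out: List[RawCnvCall] = []
    by_chrom = dict(tuple(depth.groupby("chrom", sort=False)))
    for amp in amplicons:
        sub = by_chrom.get(amp.chrom)
        if sub is None:
            total = 0.0
        else:
            # depth positions are 1-based: base i (0-based) is row pos == i+1
            mask = (sub["pos"] > amp.start) & (sub["pos"] <= amp.end)
            total = float(sub.loc[mask, "depth"].sum())
        out.append(RawCnvCall(amp.chrom, amp.start, amp.end, total / amp.length))
    return out


# ---------------------------------------------------------------------------
# SV call input
# ---------------------------------------------------------------------------

_BREAKDANCER_TYPES = {"DEL": "DEL", "INV": "INV", "ITX": "ITX", "CTX": "CTX", "DUP": "DUP"}


def read_breakdancer(path) -> List[SVCall]:
    """Read SV calls from BreakDancer native tab-separated output.

    Data columns: Chr1, Pos1, Orientation1, Chr2, Pos2, Orientation2, Type,
    Size, Score, num_Reads.  Positions are 1-based and shifted to 0-based.
    Insertion (INS) records do not join two loci and are skipped with a
    warning, as are unrecognised types.
    """
    calls: List[SVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(path, lineno, f"expected >=10 columns, got {len(fields)}")
            chrom1, pos1 = fields[0], _int_field(fields[1], path, lineno, "Pos1")
            chrom2, pos2 = fields[3], _int_field(fields[4], path, lineno, "Pos2")
            svtype = fields[6]
            if svtype == "INS":
                logger.warning("%s:%d: skipping INS record", path, lineno)
                continue
            if svtype not in _BREAKDANCER_TYPES:
                logger.warning("%s:%d: skipping unknown SV type %r", path, lineno, svtype)
                continue
            try:
                score = float(fields[8])
            except ValueError:
                score = None
            try:
                support = int(fields[9])
            except ValueError:
                support = None
            calls.append(
                SVCall.make(
                    Breakend(chrom1, pos1 - 1),
                    Breakend(chrom2, pos2 - 1),
                    _BREAKDANCER_TYPES[svtype],
                    score=score,
                    support=support,
                    source="breakdancer",
                )
            )
    return calls


_VCF_TYPE_MAP = {"DEL": "DEL", "INV": "INV", "DUP": "DUP"}


def read_delly_vcf(path, pass_only: bool = False) -> List[SVCall]:
    """Read SV calls from a Delly-style VCF.

    Uses INFO keys SVTYPE, END and (for inter-chromosomal records) CHR2.
    SVTYPE TRA/BND maps to CTX when the two chromosomes differ and ITX when
    they coincide.  FILTER is ignored unless ``pass_only`` is set.  Records
    lacking both END and CHR2 are skipped with a warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on non-VCF input
        raise ParseError(path, None, f"not a readable VCF: {exc}") from None
    calls: List[SVCall] = []
    for rec in vcf:
        if pass_only and rec.FILTER is not None:  # cyvcf2: None means PASS
            continue
        svtype = rec.INFO.get("SVTYPE")
        end = rec.INFO.get("END")
        chr2 = rec.INFO.get("CHR2")
        if end is None and chr2 is None:
            logger.warning("%s: record %s lacks both END and CHR2; skipped", path, rec.ID)
            continue
        if svtype is None:
            logger.warning("%s: record %s lacks SVTYPE; skipped", path, rec.ID)
            continue
        chrom2 = chr2 if chr2 is not None else rec.CHROM
        pos2 = int(end) - 1 if end is not None else rec.POS - 1
        if svtype in _VCF_TYPE_MAP:
            mapped = _VCF_TYPE_MAP[svtype]
        elif svtype in ("TRA", "BND"):
            mapped = "CTX" if chrom2 != rec.CHROM else "ITX"
        else:
            logger.warning("%s: skipping unknown SVTYPE %r", path, svtype)
            continue
        calls.append(
            SVCall.make(
                Breakend(rec.CHROM, rec.POS - 1),
                Breakend(chrom2, pos2),
                mapped,
                score=float(rec.QUAL) if rec.QUAL is not None else None,
                source="delly",
            )
        )
    return calls


def read_bedpe(path) -> List[SVCall]:
    """Read SV calls from generic BEDPE.

    Columns: chrom1, start1, end1, chrom2, start2, end2, name, score,
    strand1, strand2[, type].  Each breakend interval encodes positional
    uncertainty; the floor midpoint is taken as the point estimate.  The
    optional 11th column gives the SV type, else BND.
    """
    calls: List[SVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(path, lineno, f"expected >=10 columns, got {len(fields)}")
            chrom1 = fields[0]
            s1 = _int_field(fields[1], path, lineno, "start1")
            e1 = _int_field(fields[2], path, lineno, "end1")
            chrom2 = fields[3]
            s2 = _int_field(fields[4], path, lineno, "start2")
            e2 = _int_field(fields[5], path, lineno, "end2")
            svtype = fields[10] if len(fields) > 10 and fields[10] else "BND"
            try:
                score = float(fields[7])
            except ValueError:
                score = None
            calls.append(
                SVCall.make(
                    Breakend(chrom1, (s1 + e1) // 2, fields[8]),
                    Breakend(chrom2, (s2 + e2) // 2, fields[9]),
                    svtype,
                    score=score,
                    source="bedpe",
                )
            )
    return calls


#: Dispatch table for the CLI's --sv-format option.
SV_READERS = {
    "breakdancer": read_breakdancer,
    "delly-vcf": read_delly_vcf,
    "bedpe": read_bedpe,
}


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

PREDICTION_TSV_HEADER = (
    "dm_id\tcyclic\tn_amplicons\tcov_min\tcov_max\tcov_mean\tamplicons\tjunctions"
)


def _fmt_cov(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.2f}"


def _junction_str(edge, evidence, amp_by_id) -> str:
    u, v = edge
    a, b = amp_by_id[u], amp_by_id[v]
    svtype = evidence[0].svtype if evidence else "BND"
    call = evidence[0] if evidence else None
    if call is not None:
        return f"{call.end1.chrom}:{call.end1.pos}-{call.end2.chrom}:{call.end2.pos}/{svtype}"
    return f"{a.chrom}:{a.start}-{b.chrom}:{b.start}/{svtype}"


def write_outputs(predictions: Sequence[DMPrediction], out_prefix) -> List[str]:
    """Write predictions as ``<prefix>.dm.tsv``, ``<prefix>.junctions.bedpe``
    and ``<prefix>.dot``; returns the paths written.

    All three files are byte-deterministic given identical input: rows follow
    prediction order, junction and node listings are sorted, and floats are
    fixed at two decimals.
    """
    prefix = str(out_prefix)
    tsv_path = prefix + ".dm.tsv"
    bedpe_path = prefix + ".junctions.bedpe"
    dot_path = prefix + ".dot"

    with open(tsv_path, "w") as fh:
        fh.write(PREDICTION_TSV_HEADER + "\n")
        for pred in predictions:
            amp_by_id = {a.id: a for a in pred.amplicons}
            stats = pred.coverage_stats()
            cov_min, cov_max, cov_mean = stats if stats else (None, None, None)
            amps = ";".join(a.region() for a in pred.amplicons)
            juncs = ";".join(
                _junction_str(edge, ev, amp_by_id)
                for edge, ev in sorted(pred.junctions, key=lambda item: item[0])
            )
            fh.write(
                f"{pred.dm_id}\t{1 if pred.cyclic else 0}\t{pred.n_amplicons}\t"
                f"{_fmt_cov(cov_min)}\t{_fmt_cov(cov_max)}\t{_fmt_cov(cov_mean)}\t"
                f"{amps}\t{juncs}\n"
            )

    with open(bedpe_path, "w") as fh:
        for pred in predictions:
            for j, (edge, evidence) in enumerate(
                sorted(pred.junctions, key=lambda item: item[0])
            ):
                svtype = evidence[0].svtype if evidence else "BND"
                if evidence:
                    b1, b2 = evidence[0].end1, evidence[0].end2
                else:
                    amp_by_id = {a.id: a for a in pred.amplicons}
                    a, b = amp_by_id[edge[0]], amp_by_id[edge[1]]
                    b1 = Breakend(a.chrom, a.start)
                    b2 = Breakend(b.chrom, b.start)
                fh.write(
                    f"{b1.chrom}\t{b1.pos}\t{b1.pos + 1}\t"
                    f"{b2.chrom}\t{b2.pos}\t{b2.pos + 1}\t"
                    f"dm{pred.dm_id}_j{j}\t.\t.\t.\t{svtype}\n"
                )

    with open(dot_path, "w") as fh:
        fh.write("graph dm_predictions {\n")
        for pred in predictions:
            amp_by_id = {a.id: a for a in pred.amplicons}
            fh.write(f"  subgraph cluster_dm{pred.dm_id} {{\n")
            fh.write(f'    label="dm{pred.dm_id}";\n')
            for amp in sorted(pred.amplicons, key=lambda a: a.id):
                fh.write(f'    "{amp.region()}";\n')
            edges = sorted(edge for edge, _ in pred.junctions)
            for u, v in edges:
                fh.write(
                    f'    "{amp_by_id[u].region()}" -- "{amp_by_id[v].region()}";\n'
                )
            fh.write("  }\n")
        fh.write("}\n")

    return [tsv_path, bedpe_path, dot_path]


def read_predictions_tsv(path) -> List[DMPrediction]:
    """Re-read a prediction TSV written by :func:`write_outputs`.

    Amplicon order, coordinates and cyclic flags round-trip exactly; member
    coverages are not stored per amplicon in the TSV and come back ``None``.
    """
    preds: List[DMPrediction] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != PREDICTION_TSV_HEADER:
            raise ParseError(path, 1, "unrecognized prediction TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(path, lineno, f"expected 8 columns, got {len(fields)}")
            dm_id = _int_field(fields[0], path, lineno, "dm_id")
            cyclic = fields[1] == "1"
            amplicons = []
            if fields[6]:
                for i, token in enumerate(fields[6].split(";")):
                    chrom, span = token.rsplit(":", 1)
                    start, end = span.split("-")
                    amplicons.append(
                        Amplicon(
                            i, chrom,
                            _int_field(start, path, lineno, "amplicon start"),
                            _int_field(end, path, lineno, "amplicon end"),
                        )
                    )
            preds.append(DMPrediction(dm_id, amplicons, [], cyclic))
    return preds
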