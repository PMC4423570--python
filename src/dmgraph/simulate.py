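"""Caller-output emulation and detection scoring.

This module emulates the *outputs* of a copy-number caller and an SV caller
over a genome carrying known double minutes, so the detection pipeline can
be benchmarked without read simulation, alignment, or external callers.
Ground truth is a set of circular DMs, each an ordered list of amplicons
joined by junctions (consecutive plus one circle-closing).  Emulated calls
carry configurable boundary/breakend jitter, dropout, spurious SV calls and
coverage noise; coverage reflects the extra DM copies on a diploid
background as ``base * (ploidy + extra_copies) / ploidy``.

The default configuration mirrors a 20-DM, 10-amplicons-per-DM experiment
on four 50-Mb chromosomes with two extra DM copies at 35x base coverage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .io_formats import ParseError, _int_field
from .records import Amplicon, Breakend, DMPrediction, RawCnvCall, SVCall


class ConfigurationError(ValueError):
    """Raised when truth placement cannot satisfy the configuration."""


def _default_chrom_sizes() -> Dict[str, int]:
    # four synthetic chromosomes standing in for chr1, chr2, chr3, chr14
    return {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000, "chr14": 50_000_000}


@dataclass
class SimConfig:
    """Parameters of the caller-output emulator.

    Noise defaults model reasonably well-behaved callers on an amplified
    sample: ~200 bp copy-number boundary error, ~50 bp breakend error, 5%
    call dropout, 20 spurious SV calls, and mild coverage noise.  Set the
    jitter/dropout/false-call fields to zero for a noise-free run.
    """

    n_dms: int = 20
    amplicons_per_dm: int = 10
    chrom_sizes: Dict[str, int] = field(default_factory=_default_chrom_sizes)
    amplicon_len_range: Tuple[int, int] = (10_000, 200_000)
    extra_copies: int = 2          # extra DM copies beyond the diploid background
    ploidy: int = 2
    base_coverage: float = 35.0    # haploid-pair background depth (x)
    boundary_jitter_sd: float = 200.0
    breakend_jitter_sd: float = 50.0
    junction_dropout: float = 0.05
    amplicon_dropout: float = 0.05
    false_sv_count: int = 20
    coverage_noise_sd: float = 5.0
    min_gap: int = 10_000          # minimum bp between distinct true amplicons
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("junction_dropout", "amplicon_dropout"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.amplicon_len_range
        if not (0 < lo <= hi):
            raise ConfigurationError("amplicon_len_range must be positive and ordered")
        if self.n_dms < 1 or self.amplicons_per_dm < 1:
            raise ConfigurationError("n_dms and amplicons_per_dm must be >= 1")
        if self.ploidy < 1 or self.extra_copies < 0:
            raise ConfigurationError("ploidy must be >= 1, extra_copies >= 0")

    @property
    def expected_coverage(self) -> float:
        """Mean depth over an amplicon: background plus the extra copies."""
        return self.base_coverage * (self.ploidy + self.extra_copies) / self.ploidy


@dataclass
class TruthDM:
    """One ground-truth double minute.

    ``amplicons`` is the circle in order as (chrom, start, end) tuples;
    junction j joins the end of amplicon j to the start of amplicon
    j+1 (mod n), so there are exactly as many junctions as amplicons.
    """

    dm_id: int
    amplicons: List[Tuple[str, int, int]]
    junctions: List[Tuple[Tuple[str, int], Tuple[str, int]]]
    extra_copies: int

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)


def generate_truth(config: SimConfig) -> List[TruthDM]:
    """Place ``n_dms`` disjoint double minutes on the synthetic genome.

    Each amplicon is drawn uniformly (chromosome, length in
    ``amplicon_len_range``, position) and accepted only if it keeps at least
    ``min_gap`` bp from every amplicon already placed, so the downstream
    CNV-merge step cannot fuse amplicons of different DMs.  Deterministic
    for a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms = sorted(config.chrom_sizes)
    lo, hi = config.amplicon_len_range
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    truths: List[TruthDM] = []
    max_tries = 1000
    for dm_id in range(config.n_dms):
        amps: List[Tuple[str, int, int]] = []
        for _ in range(config.amplicons_per_dm):
            for attempt in range(max_tries):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = int(rng.integers(lo, hi + 1))
                limit = config.chrom_sizes[chrom] - length
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                end = start + length
                ok = all(
                    end + config.min_gap <= s or start >= e + config.min_gap
                    for s, e in placed[chrom]
                )
                if ok:
                    placed[chrom].append((start, end))
                    amps.append((chrom, start, end))
                    break
            else:
                raise ConfigurationError(
                    f"could not place amplicon after {max_tries} tries; "
                    "genome too small for the requested footprint"
                )
        n = len(amps)
        junctions = [
            ((amps[j][0], amps[j][2] - 1), (amps[(j + 1) % n][0], amps[(j + 1) % n][1]))
            for j in range(n)
        ]
        truths.append(TruthDM(dm_id, amps, junctions, config.extra_copies))
    return truths


def _jitter(rng, pos: int, sd: float, upper: Optional[int] = None) -> int:
    if sd > 0:
        pos = pos + int(round(rng.normal(0.0, sd)))
    pos = max(0, pos)
    if upper is not None:
        pos = min(pos, upper)
    return pos


def emulate_calls(
    truth: Sequence[TruthDM], config: SimConfig
) -> Tuple[List[RawCnvCall], List[SVCall]]:
    """Emulate the copy-number caller and the SV caller on the truth set.

    Per true amplicon (kept with probability 1 - amplicon_dropout): a CNV
    call with Gaussian-jittered boundaries and coverage
    ``base * (ploidy + extra) / ploidy`` plus Gaussian noise, floored at 0.
    Per true junction (kept with probability 1 - junction_dropout): an SV
    call with jittered breakends; type CTX across chromosomes, DEL for a
    reference-ordered right-end-to-left-start join on one chromosome, ITX
    otherwise.  Plus ``false_sv_count`` spurious calls with uniform random
    breakends.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    cnv_calls: List[RawCnvCall] = []
    sv_calls: List[SVCall] = []

    for dm in truth:
        for chrom, start, end in dm.amplicons:
            if rng.random() < config.amplicon_dropout:
                continue
            size = config.chrom_sizes.get(chrom)
            s = _jitter(rng, start, config.boundary_jitter_sd, size)
            e = _jitter(rng, end, config.boundary_jitter_sd, size)
            if e <= s:
                e = s + 1
            cov = config.expected_coverage
            if config.coverage_noise_sd > 0:
                cov += rng.normal(0.0, config.coverage_noise_sd)
            cnv_calls.append(RawCnvCall(chrom, s, e, round(max(0.0, cov), 4)))
        for (chrom1, pos1), (chrom2, pos2) in dm.junctions:
            if rng.random() < config.junction_dropout:
                continue
            if chrom1 != chrom2:
                svtype = "CTX"
            elif pos1 < pos2:
                svtype = "DEL"
            else:
                svtype = "ITX"
            p1 = _jitter(rng, pos1, config.breakend_jitter_sd, config.chrom_sizes.get(chrom1))
            p2 = _jitter(rng, pos2, config.breakend_jitter_sd, config.chrom_sizes.get(chrom2))
            sv_calls.append(
                SVCall.make(
                    Breakend(chrom1, p1), Breakend(chrom2, p2), svtype,
                    score=99.0, support=10, source="sim",
                )
            )

    chroms = sorted(config.chrom_sizes)
    for _ in range(config.false_sv_count):
        c1 = chroms[int(rng.integers(len(chroms)))]
        c2 = chroms[int(rng.integers(len(chroms)))]
        p1 = int(rng.integers(0, config.chrom_sizes[c1]))
        p2 = int(rng.integers(0, config.chrom_sizes[c2]))
        if c1 == c2:
            svtype = "DEL"
        else:
            svtype = "CTX"
        sv_calls.append(
            SVCall.make(
                Breakend(c1, p1), Breakend(c2, p2), svtype,
                score=30.0, support=2, source="sim-false",
            )
        )
    return cnv_calls, sv_calls


# ---------------------------------------------------------------------------
# Emitted files (dialects readable by io_formats)
# ---------------------------------------------------------------------------

def write_amplicon_bed(calls: Sequence[RawCnvCall], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            cov = "." if c.coverage is None else repr(c.coverage)
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tamp{i}\t{cov}\n")


def write_sv_bedpe(calls: Sequence[SVCall], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            score = "." if c.score is None else repr(c.score)
            fh.write(
                f"{c.end1.chrom}\t{c.end1.pos}\t{c.end1.pos + 1}\t"
                f"{c.end2.chrom}\t{c.end2.pos}\t{c.end2.pos + 1}\t"
                f"sv{i}\t{score}\t.\t.\t{c.svtype}\n"
            )


def write_sv_breakdancer(calls: Sequence[SVCall], path) -> None:
    """Emit calls in BreakDancer's native tab format (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(
            "#Chr1\tPos1\tOrientation1\tChr2\tPos2\tOrientation2\tType\tSize\t"
            "Score\tnum_Reads\n"
        )
        for c in calls:
            size = abs(c.end2.pos - c.end1.pos) if c.end1.chrom == c.end2.chrom else 0
            score = 99 if c.score is None else int(c.score)
            support = 10 if c.support is None else c.support
            fh.write(
                f"{c.end1.chrom}\t{c.end1.pos + 1}\t+\t"
                f"{c.end2.chrom}\t{c.end2.pos + 1}\t-\t"
                f"{c.svtype}\t{size}\t{score}\t{support}\n"
            )


def write_sv_vcf(calls: Sequence[SVCall], path, chrom_sizes: Optional[Dict[str, int]] = None) -> None:
    """Emit calls as a minimal Delly-style VCF (synthetic caller output).

    Intra-/inter-chromosomal translocations are written as SVTYPE=TRA with
    CHR2; DEL/INV/DUP carry SVTYPE and END on one chromosome.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">\n')
        for chrom in sorted(chrom_sizes or {}):
            fh.write(f"##contig=<ID={chrom},length={chrom_sizes[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            qual = "." if c.score is None else f"{c.score:g}"
            if c.svtype in ("CTX", "ITX", "BND"):
                info = f"SVTYPE=TRA;CHR2={c.end2.chrom};END={c.end2.pos + 1}"
                alt = "<TRA>"
            else:
                info = f"SVTYPE={c.svtype};END={c.end2.pos + 1}"
                alt = f"<{c.svtype}>"
            fh.write(
                f"{c.end1.chrom}\t{c.end1.pos + 1}\tsv{i}\tN\t{alt}\t{qual}\tPASS\t{info}\n"
            )


TRUTH_TSV_HEADER = "dm_id\textra_copies\tamplicons\tjunctions"


def write_truth_tsv(truth: Sequence[TruthDM], path) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_TSV_HEADER + "\n")
        for dm in truth:
            amps = ";".join(f"{c}:{s}-{e}" for c, s, e in dm.amplicons)
            juncs = ";".join(
                f"{c1}:{p1}-{c2}:{p2}" for (c1, p1), (c2, p2) in dm.junctions
            )
            fh.write(f"{dm.dm_id}\t{dm.extra_copies}\t{amps}\t{juncs}\n")


def read_truth_tsv(path) -> List[TruthDM]:
    truths: List[TruthDM] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TRUTH_TSV_HEADER:
            raise ParseError(path, 1, "unrecognized truth TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            amps = []
            for token in fields[2].split(";"):
                chrom, span = token.rsplit(":", 1)
                s, e = span.split("-")
                amps.append((chrom, _int_field(s, path, lineno, "start"),
                             _int_field(e, path, lineno, "end")))
            juncs = []
            if fields[3]:
                for token in fields[3].split(";"):
                    left, right = token.split("-", 1)
                    # positions are non-negative so '-' splits cleanly after chrom:pos
                    c1, p1 = left.rsplit(":", 1)
                    c2, p2 = right.rsplit(":", 1)
                    juncs.append(
                        ((c1, _int_field(p1, path, lineno, "pos")),
                         (c2, _int_field(p2, path, lineno, "pos")))
                    )
            truths.append(
                TruthDM(
                    _int_field(fields[0], path, lineno, "dm_id"),
                    amps, juncs,
                    _int_field(fields[1], path, lineno, "extra_copies"),
                )
            )
    return truths


SV_WRITERS = {
    "bedpe": write_sv_bedpe,
    "breakdancer": write_sv_breakdancer,
    "delly-vcf": write_sv_vcf,
}

_SV_SUFFIX = {"bedpe": "sv.bedpe", "breakdancer": "sv.breakdancer.txt", "delly-vcf": "sv.vcf"}


def write_sim_dir(
    truth: Sequence[TruthDM],
    cnv_calls: Sequence[RawCnvCall],
    sv_calls: Sequence[SVCall],
    config: SimConfig,
    out_dir,
    sv_format: str = "bedpe",
) -> Dict[str, str]:
    """Write the emulated dataset: amplicon BED, SV calls in the requested
    dialect, truth TSV, truth junction BEDPE, and a YAML echo of the config.
    Returns a name->path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "amplicons": str(out / "amplicons.bed"),
        "sv": str(out / _SV_SUFFIX[sv_format]),
        "truth": str(out / "truth.tsv"),
        "truth_junctions": str(out / "truth.junctions.bedpe"),
        "config": str(out / "config.yaml"),
    }
    write_amplicon_bed(cnv_calls, paths["amplicons"])
    if sv_format == "delly-vcf":
        write_sv_vcf(sv_calls, paths["sv"], chrom_sizes=config.chrom_sizes)
    else:
        SV_WRITERS[sv_format](sv_calls, paths["sv"])
    write_truth_tsv(truth, paths["truth"])
    with open(paths["truth_junctions"], "w") as fh:
        for dm in truth:
            for j, ((c1, p1), (c2, p2)) in enumerate(dm.junctions):
                fh.write(
                    f"{c1}\t{p1}\t{p1 + 1}\t{c2}\t{p2}\t{p2 + 1}\t"
                    f"truth{dm.dm_id}_j{j}\t.\t.\t.\t.\n"
                )
    cfg = dataclasses.asdict(config)
    cfg["amplicon_len_range"] = list(config.amplicon_len_range)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


@dataclass
class EvaluationResult:
    n_truth: int
    n_detected: int
    per_dm: List[dict]

    def to_dict(self) -> dict:
        return {"n_truth": self.n_truth, "n_detected": self.n_detected, "per_dm": self.per_dm}


def _match_count(pred: DMPrediction, dm: TruthDM, threshold: float) -> int:
    """Number of true amplicons of ``dm`` matched by distinct amplicons of
    ``pred`` (same chromosome, reciprocal overlap >= threshold); greedy by
    descending overlap, ties by coordinate."""
    pairs = []
    for pi, pa in enumerate(pred.amplicons):
        for ti, (chrom, s, e) in enumerate(dm.amplicons):
            if pa.chrom != chrom:
                continue
            ro = _reciprocal_overlap((pa.start, pa.end), (s, e))
            if ro >= threshold:
                pairs.append((-ro, pa.start, pa.end, s, e, pi, ti))
    pairs.sort()
    used_pred, used_true = set(), set()
    n = 0
    for _, _, _, _, _, pi, ti in pairs:
        if pi in used_pred or ti in used_true:
            continue
        used_pred.add(pi)
        used_true.add(ti)
        n += 1
    return n


def evaluate(
    truth: Sequence[TruthDM],
    predictions: Sequence[DMPrediction],
    min_match_amplicons: int = 7,
    min_reciprocal_overlap: float = 0.5,
) -> EvaluationResult:
    """Score predictions against truth.

    A truth DM counts as detected when some *single* prediction matches at
    least ``min_match_amplicons`` of its true amplicons, each match being a
    same-chromosome reciprocal overlap of at least
    ``min_reciprocal_overlap``.
    """
    per_dm = []
    n_detected = 0
    for dm in truth:
        best_n, best_pred = 0, None
        for pred in predictions:
            n = _match_count(pred, dm, min_reciprocal_overlap)
            if n > best_n:
                best_n, best_pred = n, pred.dm_id
        detected = best_n >= min_match_amplicons
        n_detected += detected
        per_dm.append(
            {
                "dm_id": dm.dm_id,
                "detected": bool(detected),
                "n_matched": best_n,
                "n_true_amplicons": dm.n_amplicons,
                "best_prediction": best_pred,
            }
        )
    return EvaluationResult(len(truth), n_detected, per_dm)
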