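"""Readers and writers for the pipeline's file formats.

VCF 4.2 breakend (BND) records are the native SV input: mated bracket records
become :class:`BreakendPair`, unmated ``.``-form records with attached sequence
become :class:`SingleBreakend`. TSV carries copy-number segments, small
variants, RNA labels and MLPA calls. A cohort is a directory of per-case files
plus ``cases.tsv``, ``ground_truth.tsv`` and ``config.json``; writers are
bit-stable given fixed input ordering.
"""
from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import pandas as pd
import pysam

from .model import (
    HEAD,
    TAIL,
    BreakendEnd,
    BreakendPair,
    Case,
    Cohort,
    CopyNumberSegment,
    GenomicInterval,
    RnaEvidence,
    SingleBreakend,
    SmallVariant,
)

_BND_RE = re.compile(r"^([ACGTNacgtn]*)([\[\]])([^:\[\]]+):(\d+)([\[\]])([ACGTNacgtn]*)$")


class VcfRecordError(ValueError):
    pass


def _decode_bnd_alt(alt: str, record_no: int) -> tuple[str, str, int, str, str]:
    """Decode a bracketed BND ALT.

    Returns (local_orientation, mate_chrom, mate_pos, mate_orientation,
    inserted_seq). ``tail`` = left side of the breakpoint retained.
    """
    m = _BND_RE.match(alt)
    if not m or m.group(2) != m.group(5):
        raise VcfRecordError(f"record {record_no}: malformed bracket ALT {alt!r}")
    left, br, mate_chrom, mate_pos, _, right = m.groups()
    if bool(left) == bool(right):
        raise VcfRecordError(f"record {record_no}: bracket ALT {alt!r} must have bases on exactly one side")
    if left:  # t[p[ or t]p] : local left side retained
        local = TAIL
        mate = HEAD if br == "[" else TAIL
        inserted = left[1:]  # first base is the REF anchor base
    else:  # ]p]t or [p[t : local right side retained
        local = HEAD
        mate = TAIL if br == "]" else HEAD
        inserted = right[:-1]
    return local, mate_chrom, int(mate_pos), mate, inserted


def _encode_bnd_alt(ref: str, local: str, mate: BreakendEnd, inserted: str) -> str:
    loc = f"{mate.chrom}:{mate.pos}"
    if local == TAIL:
        br = "[" if mate.orientation == HEAD else "]"
        return f"{ref}{inserted}{br}{loc}{br}"
    br = "]" if mate.orientation == TAIL else "["
    return f"{br}{loc}{br}{inserted}{ref}"


def read_sv_vcf(path: str | Path) -> tuple[list[BreakendPair], list[SingleBreakend]]:
    """Parse BND-notation SVs: mated pairs and single breakends.

    Mated records are paired via MATEID; unmated records carrying attached
    sequence (``s.`` / ``.s`` ALT) become single breakends; unmated bracket
    records without a mate are skipped with a warning.
    """
    pairs: list[BreakendPair] = []
    singles: list[SingleBreakend] = []
    pending: dict[str, tuple] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for record_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            alt = rec.alts[0] if rec.alts else ""
            rid = rec.id or f"rec{record_no}"
            if alt.startswith(".") or alt.endswith("."):
                seq = alt.strip(".")
                orientation = TAIL if alt.endswith(".") else HEAD
                if not seq:
                    raise VcfRecordError(f"record {record_no}: single breakend with no attached sequence")
                singles.append(
                    SingleBreakend(rid, BreakendEnd(rec.chrom, rec.pos, orientation), seq)
                )
                continue
            local, mchrom, mpos, morient, inserted = _decode_bnd_alt(alt, record_no)
            mateid = rec.info.get("MATEID")
            if isinstance(mateid, tuple):
                mateid = mateid[0]
            end = BreakendEnd(rec.chrom, rec.pos, local)
            if mateid and mateid in pending:
                other_end, other_ins, other_id = pending.pop(mateid)
                sv_id = _shared_id(other_id, rid)
                pairs.append(BreakendPair(sv_id, other_end, end, inserted_seq=other_ins or inserted))
            elif mateid:
                pending[rid] = (end, inserted, rid)
            else:
                warnings.warn(f"record {record_no} ({rid}): BND mate not found, skipping")
    for rid, (end, _ins, _r) in pending.items():
        warnings.warn(f"BND record {rid}: mate not found, skipping")
    return pairs, singles


def _shared_id(id1: str, id2: str) -> str:
    for suf in ("_1", "_2", "a", "b"):
        if id1.endswith(suf) and id1[: -len(suf)] == id2[: -len(suf)]:
            return id1[: -len(suf)]
    return id1


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=SVCLASS,Number=1,Type=String,Description="SV class">
"""


def write_sv_vcf(
    path: str | Path,
    pairs: list[BreakendPair],
    singles: list[SingleBreakend],
    contig_lengths: dict[str, int],
) -> None:
    lines = [_VCF_HEADER]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    rows = []
    for p in pairs:
        for k, (end, mate) in enumerate(((p.end1, p.end2), (p.end2, p.end1))):
            rid, mid = f"{p.id}_{k + 1}", f"{p.id}_{2 - k}"
            alt = _encode_bnd_alt("N", end.orientation, mate, p.inserted_seq if k == 0 else "")
            info = f"SVTYPE=BND;MATEID={mid};SVCLASS={p.svclass}"
            rows.append((end.chrom, end.pos, rid, "N", alt, info))
    for s in singles:
        seq = s.attached_seq
        alt = f"{seq}." if s.locus.orientation == TAIL else f".{seq}"
        ref = seq[0] if s.locus.orientation == TAIL else seq[-1]
        rows.append((s.locus.chrom, s.locus.pos, s.id, ref, alt, "SVTYPE=BND"))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    for chrom, pos, rid, ref, alt, info in rows:
        lines.append(f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    segs = [
        CopyNumberSegment(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            int(r.total_cn),
            int(r.minor_cn),
            float(r.ccf),
        )
        for r in df.itertuples()
    ]
    segs.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    for a, b in zip(segs, segs[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start <= a.interval.end:
            raise ValueError(
                "overlapping copy-number segments "
                f"{a.interval.chrom}:{a.interval.start}-{a.interval.end} and "
                f"{b.interval.chrom}:{b.interval.start}-{b.interval.end}"
            )
    return segs


def write_segments(path: str | Path, segments: list[CopyNumberSegment]) -> None:
    rows = [
        {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "total_cn": s.total_cn,
            "minor_cn": s.minor_cn,
            "ccf": s.ccf,
        }
        for s in sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn", "ccf"]).to_csv(
        path, sep="\t", index=False
    )


def read_small_variants(path: str | Path) -> list[SmallVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "protein_change": str}, keep_default_na=False)
    return [
        SmallVariant(
            (r.chrom, int(r.pos)),
            r.ref,
            r.alt,
            float(r.vaf),
            r.gene,
            r.protein_change,
            r.classification,
        )
        for r in df.itertuples()
    ]


def write_small_variants(path: str | Path, variants: list[SmallVariant]) -> None:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vaf": round(v.vaf, 4),
            "gene": v.gene,
            "protein_change": v.protein_change,
            "classification": v.classification,
        }
        for v in variants
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "vaf", "gene", "protein_change", "classification"]
    ).to_csv(path, sep="\t", index=False)


def write_rna(path: str | Path, rna: RnaEvidence) -> None:
    payload = {
        "classifier_labels": rna.classifier_labels,
        "cluster_label": rna.cluster_label,
        "fusions": [list(f) for f in rna.fusions],
        "quality_flags": sorted(rna.quality_flags),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_rna(path: str | Path) -> RnaEvidence:
    d = json.loads(Path(path).read_text())
    return RnaEvidence(
        classifier_labels=d["classifier_labels"],
        cluster_label=d["cluster_label"],
        fusions=[tuple(f) for f in d["fusions"]],
        quality_flags=set(d["quality_flags"]),
    )


def write_mlpa(path: str | Path, calls: dict[str, str]) -> None:
    pd.DataFrame(
        [{"gene": g, "call": c} for g, c in sorted(calls.items())], columns=["gene", "call"]
    ).to_csv(path, sep="\t", index=False)


def read_mlpa(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.gene, df.call))


def read_genes_bed(path: str | Path) -> dict[str, GenomicInterval]:
    """BED6 gene models (0-based half-open on disk -> 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"], dtype={"chrom": str},
    )
    return {
        r.name: GenomicInterval(r.chrom, int(r.start) + 1, int(r.end), r.strand)
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# cohort directory
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path, contig_lengths: dict[str, int]) -> None:
    outdir = Path(outdir)
    (outdir / "cases").mkdir(parents=True, exist_ok=True)
    meta = []
    for case in sorted(cohort.cases, key=lambda c: c.case_id):
        base = outdir / "cases" / case.case_id
        write_sv_vcf(f"{base}.sv.vcf", case.svs, case.single_breakends, contig_lengths)
        write_segments(f"{base}.segments.tsv", case.segments)
        write_small_variants(f"{base}.smallvars.tsv", case.small_variants)
        if case.rna is not None:
            write_rna(f"{base}.rna.json", case.rna)
        if case.mlpa is not None:
            write_mlpa(f"{base}.mlpa.tsv", case.mlpa)
        meta.append(
            {
                "case_id": case.case_id,
                "age": case.age,
                "sex": case.sex,
                "karyotype_class": case.karyotype_class,
                "purity": "" if case.purity is None else case.purity,
            }
        )
    pd.DataFrame(meta).to_csv(outdir / "cases.tsv", sep="\t", index=False)
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    if cohort.config is not None:
        (outdir / "config.json").write_text(json.dumps(cohort.config, indent=1, sort_keys=True) + "\n")


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    meta = pd.read_csv(indir / "cases.tsv", sep="\t", dtype={"case_id": str})
    cases = []
    for r in meta.itertuples():
        base = indir / "cases" / r.case_id
        if not Path(f"{base}.sv.vcf").exists():
            raise FileNotFoundError(f"missing per-case file {base}.sv.vcf")
        svs, singles = read_sv_vcf(f"{base}.sv.vcf")
        case = Case(
            case_id=r.case_id,
            age=float(r.age),
            sex=r.sex,
            karyotype_class=r.karyotype_class,
            purity=None if pd.isna(r.purity) else float(r.purity),
            svs=svs,
            single_breakends=singles,
            segments=read_segments(f"{base}.segments.tsv"),
            small_variants=read_small_variants(f"{base}.smallvars.tsv"),
        )
        if Path(f"{base}.rna.json").exists():
            case.rna = read_rna(f"{base}.rna.json")
        if Path(f"{base}.mlpa.tsv").exists():
            case.mlpa = read_mlpa(f"{base}.mlpa.tsv")
        cases.append(case)
    gt_path = indir / "ground_truth.tsv"
    gt = pd.read_csv(gt_path, sep="\t") if gt_path.exists() else None
    cfg_path = indir / "config.json"
    cfg = json.loads(cfg_path.read_text()) if cfg_path.exists() else None
    return Cohort(cases, ground_truth=gt, config=cfg)
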