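"""Mutational-signature refitting, the somatic mutation clock, and RAG
RSS-motif annotation of deletion breakpoints.

The single-base-substitution catalog uses the standard 96-context convention:
six pyrimidine substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) by sixteen
flanking-base contexts; purine-reference SNVs are reverse-complement folded.
Exposures against the packaged 7-signature reference are obtained by
non-negative least squares, with the cosine similarity of the reconstruction
reported alongside. The mutation clock regresses per-case autosomal SNV burden
on age with a Huber robust linear model after excluding hypermutators, which
matches how a clock-like blood signature accumulating ~constant mutations per
year is normally quantified.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm

from .model import BreakendPair, Case, SmallVariant
from .sequtils import revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in "ACGT" for three in "ACGT"
)
_BIN_OF = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

RSS_HEPTAMER = "CACAGTG"


def fold(tri: str, alt: str) -> tuple[str, str]:
    """Fold a ref trinucleotide + alt base to the pyrimidine-centred strand."""
    if tri[1] in "CT":
        return tri, alt
    return revcomp(tri), revcomp(alt)


def bin_index(tri: str, alt: str) -> int:
    tri, alt = fold(tri, alt)
    return _BIN_OF[f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"]


def load_reference() -> pd.DataFrame:
    """Packaged 96x7 signature reference, columns L1-normalized."""
    with resources.files("leukotype.data").joinpath("signatures_sbs7.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="context")
    return df


def build_catalog(snvs: list[SmallVariant], reference) -> np.ndarray:
    """96-bin catalog from SNVs; ``reference`` provides ``fetch(chrom, start, end)``.

    Raises if any SNV's ref allele disagrees with the reference base.
    """
    counts = np.zeros(96, dtype=np.int64)
    mismatches = []
    for v in snvs:
        if v.classification != "SNV":
            continue
        tri = reference.fetch(v.chrom, v.pos - 1, v.pos + 1)
        if tri[1] != v.ref:
            mismatches.append(f"{v.chrom}:{v.pos} ref {v.ref} vs genome {tri[1]}")
            continue
        counts[bin_index(tri, v.alt)] += 1
    if mismatches:
        raise ValueError("reference mismatch at " + "; ".join(mismatches[:10]))
    return counts


@dataclass
class SignatureExposure:
    exposures: np.ndarray  # per-signature mutation counts, >= 0
    fractions: np.ndarray | None  # sums to 1, None when catalog empty
    reconstruction_cosine: float
    signature_names: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_names, self.exposures))


def cosine(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for zero vector")
    return float(a @ b / (na * nb))


def refit(catalog: np.ndarray, reference_signatures: pd.DataFrame) -> SignatureExposure:
    """Non-negative least squares refit of a catalog onto reference signatures.

    exposures = argmin_{e >= 0} || catalog - S e ||_2 with S the 96 x k
    column-normalized reference matrix.
    """
    catalog = np.asarray(catalog, dtype=float)
    S = reference_signatures.to_numpy(dtype=float)
    names = tuple(reference_signatures.columns)
    if catalog.sum() == 0:
        return SignatureExposure(np.zeros(S.shape[1]), None, float("nan"), names)
    exposures, _ = scipy.optimize.nnls(S, catalog)
    recon = S @ exposures
    return SignatureExposure(
        exposures, exposures / exposures.sum(), cosine(catalog, recon), names
    )


@dataclass
class ClockFit:
    slope: float  # mutations per year
    intercept: float
    ci_low: float
    ci_high: float
    outliers: tuple[str, ...]
    n_used: int


def flag_hypermutator(
    burdens: dict[str, int], fold: float = 10.0, floor: int = 10_000
) -> list[str]:
    """Case ids with SNV burden above max(``fold`` x cohort median, ``floor``)."""
    if len(burdens) < 5:
        raise ValueError("need at least 5 cases")
    med = float(np.median(list(burdens.values())))
    cut = max(fold * med, floor)
    return sorted(cid for cid, n in burdens.items() if n > cut)


def fit_clock(
    burden_by_case: dict[str, int],
    ages: dict[str, float],
    exclude_outliers: bool = True,
) -> ClockFit:
    """Huber robust linear fit of SNV burden on age (tuning constant 1.345),
    with an asymptotic-normal 95% CI on the slope."""
    if len(burden_by_case) < 10:
        raise ValueError("need at least 10 cases for the clock fit")
    outliers: tuple[str, ...] = ()
    if exclude_outliers:
        outliers = tuple(flag_hypermutator(burden_by_case))
    ids = [c for c in burden_by_case if c not in outliers]
    y = np.array([burden_by_case[c] for c in ids], dtype=float)
    x = sm.add_constant(np.array([ages[c] for c in ids], dtype=float))
    model = sm.RLM(y, x, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit()
    slope, se = res.params[1], res.bse[1]
    return ClockFit(
        slope=float(slope),
        intercept=float(res.params[0]),
        ci_low=float(slope - 1.959964 * se),
        ci_high=float(slope + 1.959964 * se),
        outliers=outliers,
        n_used=len(ids),
    )


# ---------------------------------------------------------------------------
# RAG RSS-motif annotation
# ---------------------------------------------------------------------------

def _rss_window_hit(seq: str, max_mismatch: int) -> bool:
    """Any <= ``max_mismatch`` occurrence of the RSS heptamer on either strand."""
    for motif in (RSS_HEPTAMER, revcomp(RSS_HEPTAMER)):
        m = len(motif)
        if len(seq) < m:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        pat = np.frombuffer(motif.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        if (windows != pat).sum(axis=1).min() <= max_mismatch:
            return True
    return False


def rss_at_breakpoint(
    reference, chrom: str, pos: int, window: int = 25, max_mismatch: int = 1
) -> bool:
    """RSS heptamer within +-``window`` bp of a breakpoint position.

    The scanned sequence covers every heptamer start within the window on
    either side of ``pos``.
    """
    length = len(reference.seq(chrom))
    lo = max(1, pos - window)
    hi = min(length, pos + window + len(RSS_HEPTAMER) - 1)
    return _rss_window_hit(reference.fetch(chrom, lo, hi), max_mismatch)


@dataclass
class RagAnnotation:
    flags: dict[str, bool]  # sv id -> RAG attributed
    burden: int
    total_deletions: int

    @property
    def fraction(self) -> float:
        return self.burden / self.total_deletions if self.total_deletions else 0.0


def annotate_rag(
    deletions: list[BreakendPair],
    reference,
    window: int = 25,
    max_mismatch: int = 1,
    max_size: int = 1_000_000,
) -> RagAnnotation:
    """Flag deletions with a cryptic RSS heptamer near either breakpoint.

    Only deletions below ``max_size`` are considered, mirroring the size scale
    of V(D)J-recombinase off-target events.
    """
    flags: dict[str, bool] = {}
    for sv in deletions:
        if sv.svclass != "deletion" or sv.span >= max_size:
            continue
        flags[sv.id] = any(
            rss_at_breakpoint(reference, e.chrom, e.pos, window, max_mismatch)
            for e in (sv.end1, sv.end2)
        )
    burden = sum(flags.values())
    return RagAnnotation(flags, burden, len(flags))


def case_rag_annotation(case: Case, reference, **kwargs) -> RagAnnotation:
    dels = [sv for sv in case.svs if sv.svclass == "deletion"]
    return annotate_rag(dels, reference, **kwargs)
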