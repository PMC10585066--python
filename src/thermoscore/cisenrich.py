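"""Promoter cis-element scanning and resampling enrichment z-statistic.

Five heat-stress elements are built in: the complete heat-shock element
(nGAAn)(nTTCn)(nGGAn), the partial HSE (nGAAn)(nTTCn), the dehydration-
responsive element A/GCCGAC, the abscisic-acid responsive element ACGTGG/T
and the evening element AAAATATCT.  Enrichment of an element in a focal gene
set (typically the top-100 upregulated genes) is expressed as

    z = (N - mu) / sigma

where N is the total occurrence count in the focal promoters and mu, sigma
are the mean and SD of that count over repeated random same-size gene sets
drawn from the whole promoter universe (default 100 genes x 1000 draws).

Matching conventions: overlapping occurrences all count; the degenerate
motif symbol N matches any unambiguous base but an N in the *sequence*
matches nothing; scanning is forward-strand only by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io import Motif, PromoterSet, ValidationError, get_logger

__all__ = [
    "MOTIF_REGISTRY",
    "EnrichmentResult",
    "compile_motif",
    "count_occurrences",
    "observed_count",
    "per_promoter_counts",
    "resample_null",
    "resample_null_from_counts",
    "enrichment_z",
    "enrich",
]

log = get_logger("cisenrich")

MOTIF_REGISTRY: dict[str, Motif] = {
    "complete_HSE": Motif("complete_HSE", ("NGAAN", "NTTCN", "NGGAN")),
    "partial_HSE": Motif("partial_HSE", ("NGAAN", "NTTCN")),
    "DRE": Motif("DRE", ("RCCGAC",)),
    "ABRE": Motif("ABRE", ("ACGTGK",)),
    "EE": Motif("EE", ("AAAATATCT",)),
}

# motif symbol -> the concrete sequence bases it accepts (sequence N never matches)
_SYMBOL_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "N": "ACGT", "R": "AG", "K": "GT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompiledMotif:
    """A motif compiled to an overlap-aware regular expression."""

    motif: Motif
    regex: re.Pattern
    length: int

    def match_starts(self, seq: str) -> list[int]:
        return [m.start() for m in self.regex.finditer(seq)]


def compile_motif(spec: Motif) -> CompiledMotif:
    """Compile a degenerate motif into a scanner for overlapping occurrences."""
    pattern = spec.pattern
    try:
        body = "".join(
            ch if ch in "ACGT" else f"[{_SYMBOL_BASES[ch]}]" for ch in pattern
        )
    except KeyError as e:  # Motif validation normally precludes this
        raise ValidationError(f"invalid motif symbol {e.args[0]!r}") from None
    # lookahead so that overlapping starts are all reported
    return CompiledMotif(motif=spec, regex=re.compile(f"(?=({body}))"), length=len(pattern))


_SEQ_ALPHABET = frozenset("ACGTN")


def count_occurrences(seq: str, matcher: CompiledMotif, strand_mode: str = "forward") -> int:
    """Count all (possibly overlapping) occurrence start positions in ``seq``.

    In ``both`` mode, reverse-complement matches are added; an occurrence
    whose footprint matches on both strands because the site is its own
    reverse complement is counted once.
    """
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValidationError(f"invalid sequence character(s): {sorted(bad)}")
    fwd = matcher.match_starts(seq)
    if strand_mode == "forward":
        return len(fwd)
    if strand_mode != "both":
        raise ValidationError(f"strand_mode must be forward|both, got {strand_mode!r}")
    L, m = len(seq), matcher.length
    rev = {L - j - m for j in matcher.match_starts(reverse_complement(seq))}
    palindromic = sum(
        1
        for i in set(fwd) & rev
        if reverse_complement(seq[i : i + m]) == seq[i : i + m]
    )
    return len(fwd) + len(rev) - palindromic


def observed_count(
    gene_set: list[str],
    promoters: PromoterSet,
    matcher: CompiledMotif,
    strand_mode: str = "forward",
) -> tuple[int, int]:
    """Total occurrence count N over the set's promoters.

    Genes lacking a promoter are dropped with a warning; returns
    ``(N, effective_set_size)``.
    """
    present = [g for g in gene_set if g in promoters]
    dropped = [g for g in gene_set if g not in promoters]
    if dropped:
        log.warning("%d gene(s) lack a promoter and were dropped: %s ...",
                    len(dropped), dropped[:5])
    if not present:
        raise ValidationError("no gene in the focal set has a promoter")
    n = sum(count_occurrences(promoters[g], matcher, strand_mode) for g in present)
    return n, len(present)


def per_promoter_counts(
    promoters: PromoterSet, matcher: CompiledMotif, strand_mode: str = "forward"
) -> tuple[list[str], np.ndarray]:
    """Occurrence count of the motif in every promoter of the universe."""
    genes = list(promoters)
    counts = np.array(
        [count_occurrences(promoters[g], matcher, strand_mode) for g in genes],
        dtype=float,
    )
    return genes, counts


def resample_null_from_counts(
    counts: np.ndarray, set_size: int, reps: int, seed: int
) -> tuple[float, float, np.ndarray]:
    """Null distribution of the set-total count over random gene sets.

    Each draw picks ``set_size`` distinct genes uniformly from the full
    universe (focal genes are not excluded) and totals their per-promoter
    counts; returns ``(mu, sigma, null_counts)`` with sigma at ddof=1.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < set_size:
        raise ValidationError(
            f"promoter universe ({len(counts)}) smaller than set_size ({set_size})"
        )
    rng = np.random.default_rng(seed)
    g = len(counts)
    nulls = np.empty(reps, dtype=float)
    for r in range(reps):
        idx = rng.choice(g, size=set_size, replace=False)
        nulls[r] = counts[idx].sum()
    return float(nulls.mean()), float(nulls.std(ddof=1)), nulls


def resample_null(
    promoters: PromoterSet,
    matcher: CompiledMotif,
    set_size: int = 100,
    reps: int = 1000,
    seed: int = 0,
    strand_mode: str = "forward",
) -> tuple[float, float, np.ndarray]:
    """As :func:`resample_null_from_counts`, scanning the universe first."""
    if len(promoters) < set_size:
        raise ValidationError(
            f"promoter universe ({len(promoters)}) smaller than set_size ({set_size})"
        )
    _, counts = per_promoter_counts(promoters, matcher, strand_mode)
    return resample_null_from_counts(counts, set_size, reps, seed)


def enrichment_z(n_observed: float, mu: float, sigma: float) -> float:
    """z = (N - mu) / sigma; errors on a degenerate (zero-variance) null."""
    if sigma <= 0:
        raise ValidationError("degenerate null: sigma must be > 0")
    return (n_observed - mu) / sigma


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed count, null moments and z for one motif on one gene set."""

    motif: str
    gene_set_size: int
    n_observed: int
    mu: float
    sigma: float
    z: float
    reps: int
    seed: int


def enrich(
    gene_set: list[str],
    promoters: PromoterSet,
    motif: Motif,
    set_size: int | None = None,
    reps: int = 1000,
    seed: int = 0,
    strand_mode: str = "forward",
) -> EnrichmentResult:
    """Full enrichment of one motif in one focal gene set.

    The null set size defaults to the focal set's effective size, so that
    observed and null totals are over equally many promoters.
    """
    matcher = compile_motif(motif)
    n, eff = observed_count(gene_set, promoters, matcher, strand_mode)
    mu, sigma, _ = resample_null(
        promoters, matcher,
        set_size=set_size if set_size is not None else eff,
        reps=reps, seed=seed, strand_mode=strand_mode,
    )
    return EnrichmentResult(
        motif=motif.name, gene_set_size=eff, n_observed=n,
        mu=mu, sigma=sigma, z=enrichment_z(n, mu, sigma),
        reps=reps, seed=seed,
    )
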