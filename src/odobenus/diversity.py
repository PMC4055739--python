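"""Haplotype collapsing and diversity/divergence statistics for mtDNA alignments.

Aligned control-region sequences are collapsed to haplotypes on the
*analysed sites*: by default every alignment column containing a gap,
ambiguity code or N in any sequence is excluded (complete deletion), and
sequences identical on the remaining columns merge.  From the per-region
haplotype frequencies the module computes

* haplotype diversity ``h = n(1 - sum p_i^2)/(n - 1)`` with Nei's sampling
  variance,
* per-site nucleotide diversity ``pi`` with Nei's no-recombination sampling
  variance, and
* mean pairwise difference counts ``k`` within and between regions,

which satisfy ``pi * (number of analysed sites) = k_within`` exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from odobenus.io import DataError, RegionAlignment

_ACGT = frozenset("ACGT")


@dataclass
class HaplotypeTable:
    """Distinct sequences (restricted to analysed sites) with regional counts."""

    haplotypes: list[tuple[str, str]]  # (hap_id, sequence over analysed sites)
    counts: dict[tuple[str, str], int]  # (hap_id, region) -> count
    analysed_sites: list[int]  # 1-based alignment column indices
    full_sequences: dict[str, str] = field(default_factory=dict)  # hap_id -> full seq

    @property
    def n_sites(self) -> int:
        return len(self.analysed_sites)

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for _, region in self.counts:
            if region not in seen:
                seen.append(region)
        return seen

    def region_counts(self, region: str) -> dict[str, int]:
        return {
            hap: c for (hap, r), c in self.counts.items() if r == region and c > 0
        }

    def region_n(self, region: str) -> int:
        return sum(self.region_counts(region).values())

    def sequence(self, hap_id: str) -> str:
        for hid, seq in self.haplotypes:
            if hid == hap_id:
                return seq
        raise KeyError(hap_id)


@dataclass
class DiversityStats:
    region: str
    n: int
    n_haplotypes: int
    h: float
    h_se: float
    pi: float
    pi_se: float
    k_within: float


@dataclass
class DivergenceMatrix:
    """Symmetric region x region mean pairwise differences; diagonal = within."""

    regions: list[str]
    values: dict[tuple[str, str], float]

    def get(self, a: str, b: str) -> float:
        return self.values.get((a, b), self.values.get((b, a), float("nan")))


# ---------------------------------------------------------------------------
# collapsing


def analysed_site_indices(sequences: list[str], pairwise: bool = False) -> list[int]:
    """0-based indices of columns usable for comparison.

    Complete deletion (default): a column is kept only if every sequence has
    an unambiguous A/C/G/T there.  ``pairwise=True`` keeps all columns (the
    per-pair handling is then the caller's concern; not used by default).
    """
    if pairwise:
        return list(range(len(sequences[0])))
    keep = []
    for j in range(len(sequences[0])):
        if all(seq[j] in _ACGT for seq in sequences):
            keep.append(j)
    return keep


def collapse_haplotypes(
    aln: RegionAlignment, truncate_to: int | None = None
) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes on the analysed sites.

    ``truncate_to`` first trims every sequence to a common leading window
    (emulating shorter reads collapsing otherwise-distinct haplotypes).
    Haplotype ids are ``<region><ordinal>`` where region is the region of
    first occurrence and ordinals follow input order.
    """
    if truncate_to is not None:
        if truncate_to > aln.length or truncate_to < 1:
            raise DataError(f"truncate_to {truncate_to} outside [1, {aln.length}]")
        records = [(sid, reg, seq[:truncate_to]) for sid, reg, seq in aln.records]
    else:
        records = list(aln.records)
    seqs = [seq for _, _, seq in records]
    keep = analysed_site_indices(seqs)
    if not keep:
        raise DataError("no analysed sites remain after complete deletion")
    key_of = {}
    order: list[str] = []  # core sequences by first occurrence
    counts: dict[tuple[str, str], int] = {}
    first_region: dict[str, str] = {}
    full_of: dict[str, str] = {}
    for sid, region, seq in records:
        core = "".join(seq[j] for j in keep)
        if core not in key_of:
            key_of[core] = core
            order.append(core)
            first_region[core] = region
            full_of[core] = seq
        counts[(core, region)] = counts.get((core, region), 0) + 1
    per_region_ordinal: dict[str, int] = {}
    hap_ids: dict[str, str] = {}
    for core in order:
        region = first_region[core]
        per_region_ordinal[region] = per_region_ordinal.get(region, 0) + 1
        hap_ids[core] = f"{region}{per_region_ordinal[region]}"
    return HaplotypeTable(
        haplotypes=[(hap_ids[c], c) for c in order],
        counts={(hap_ids[c], r): n for (c, r), n in counts.items()},
        analysed_sites=[j + 1 for j in keep],
        full_sequences={hap_ids[c]: full_of[c] for c in order},
    )


# ---------------------------------------------------------------------------
# diversity estimators


def haplotype_diversity(counts: list[int]) -> tuple[float, float]:
    """Unbiased haplotype diversity and its standard error (Nei 1987).

    h = n(1 - sum p_i^2)/(n - 1);
    V(h) = 2/(n(n-1)) * {2(n-2)[sum p_i^3 - (sum p_i^2)^2] + sum p_i^2 - (sum p_i^2)^2}.
    """
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise DataError("haplotype diversity needs n >= 2")
    p = np.asarray(counts, dtype=float) / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def _pair_diffs(ht: HaplotypeTable) -> dict[tuple[str, str], int]:
    """Mismatch counts between all haplotype pairs (analysed sites)."""
    diffs: dict[tuple[str, str], int] = {}
    for (id_a, seq_a), (id_b, seq_b) in itertools.combinations(ht.haplotypes, 2):
        d = sum(1 for x, y in zip(seq_a, seq_b) if x != y)
        diffs[(id_a, id_b)] = d
    return diffs


def _diff(diffs: dict, a: str, b: str) -> int:
    if a == b:
        return 0
    return diffs.get((a, b), diffs.get((b, a), 0))


def mean_pairwise_within(ht: HaplotypeTable, region: str) -> float:
    """Mean mismatch count over all C(n, 2) sample pairs within a region."""
    counts = ht.region_counts(region)
    n = sum(counts.values())
    if n < 2:
        raise DataError(f"region {region!r}: need n >= 2")
    diffs = _pair_diffs(ht)
    total = 0.0
    for (a, ca), (b, cb) in itertools.combinations(counts.items(), 2):
        total += ca * cb * _diff(diffs, a, b)
    return total / (n * (n - 1) / 2.0)


def mean_pairwise_between(ht: HaplotypeTable, region_a: str, region_b: str) -> float:
    """Mean mismatch count over all n_A x n_B cross-region sample pairs."""
    ca = ht.region_counts(region_a)
    cb = ht.region_counts(region_b)
    if not ca or not cb:
        raise DataError("both regions must be non-empty")
    diffs = _pair_diffs(ht)
    total = sum(
        na * nb * _diff(diffs, a, b) for a, na in ca.items() for b, nb in cb.items()
    )
    return total / (sum(ca.values()) * sum(cb.values()))


def nucleotide_diversity(ht: HaplotypeTable, region: str) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard error.

    pi = n/(n-1) * sum_{i != j} x_i x_j pi_ij  (x: relative haplotype
    frequencies, pi_ij: per-analysed-site difference proportion), which
    equals k_within / L.  The variance is Nei's (1987) sampling formula for
    non-recombining sequences:
    V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2.
    """
    n = ht.region_n(region)
    if n < 2:
        raise DataError(f"region {region!r}: need n >= 2")
    L = ht.n_sites
    if L == 0:
        raise DataError("no analysed sites")
    pi = mean_pairwise_within(ht, region) / L
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0)))


def diversity_report(
    ht: HaplotypeTable,
) -> tuple[list[DiversityStats], DivergenceMatrix]:
    """Per-region diversity statistics plus the full divergence matrix.

    Regions with n < 2 are reported with counts only (diversity fields NaN)
    and omitted from within-region divergence entries.
    """
    regions = ht.regions
    stats_rows: list[DiversityStats] = []
    values: dict[tuple[str, str], float] = {}
    for region in regions:
        counts = ht.region_counts(region)
        n = sum(counts.values())
        if n >= 2:
            h, h_se = haplotype_diversity(list(counts.values()))
            pi, pi_se = nucleotide_diversity(ht, region)
            k = mean_pairwise_within(ht, region)
            values[(region, region)] = k
        else:
            h = h_se = pi = pi_se = k = float("nan")
        stats_rows.append(
            DiversityStats(region, n, len(counts), h, h_se, pi, pi_se, k)
        )
    for a, b in itertools.combinations(regions, 2):
        values[(a, b)] = mean_pairwise_between(ht, a, b)
    return stats_rows, DivergenceMatrix(regions=regions, values=values)
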