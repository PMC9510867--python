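"""High-confidence callset construction: exclusion filtering + retention tiers.

The integration recipe keeps a merged multi-platform call when either
support tier holds:

* anchored tier — the call was detected by the anchor platform (CCS) and
  corroborated by at least one of the corroborating platforms (CLR, ONT);
* long-SV tier — the call is longer than 1.5 kb and supported by both the
  assembly-based callset (ASM) and optical mapping (BN).

Calls intersecting the supplied exclusion regions (centromeres, telomeres,
segmental duplications, short tandem repeats — a user-supplied BED) are
removed first; calls below the 50 bp structural-variant floor never pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .matching import SVMERGE_DEFAULT, MatchParams, cluster_merge
from .model import PLATFORMS, Callset, RegionSet


@dataclass(frozen=True)
class RetentionPolicy:
    """The two cross-platform support tiers plus the SV size floor."""

    anchor_label: str = "CCS"
    corroborating_labels: frozenset = frozenset({"CLR", "ONT"})
    long_sv_min_len: int = 1500
    long_sv_labels: frozenset = frozenset({"ASM", "BN"})
    min_svlen: int = 50

    def __post_init__(self):
        if self.long_sv_min_len <= self.min_svlen:
            raise ValueError("long_sv_min_len must exceed min_svlen")

    def known_labels(self) -> set:
        return set(PLATFORMS) | {self.anchor_label} | set(self.corroborating_labels) | set(
            self.long_sv_labels
        )

    def retains(self, support: set, svlen: int) -> bool:
        if svlen < self.min_svlen:
            return False
        anchored = self.anchor_label in support and bool(
            support & set(self.corroborating_labels)
        )
        long_sv = svlen > self.long_sv_min_len and set(self.long_sv_labels) <= support
        return anchored or long_sv


def filter_excluded_regions(cs: Callset, excl: RegionSet) -> tuple[Callset, Callset]:
    """Split a callset by intersection with exclusion regions.

    A deletion is removed when its span [start, end) intersects any
    exclusion interval; an insertion when its breakpoint falls inside one.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in excl.normalize().intervals:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    kept, removed = [], []
    for rec in cs:
        s, e = rec.span()
        tree = trees.get(rec.chrom)
        (removed if tree is not None and tree.overlap(s, e) else kept).append(rec)
    return (
        Callset(cs.label, kept, dict(cs.meta)).sort(),
        Callset(f"{cs.label}_excluded", removed).sort(),
    )


def apply_retention_rules(cs: Callset, policy: RetentionPolicy = RetentionPolicy()) -> Callset:
    """Keep records satisfying either support tier (and the size floor)."""
    known = policy.known_labels()
    for rec in cs:
        unknown = rec.support - known
        if unknown:
            raise ValueError(f"{rec.id}: unknown platform label(s) {sorted(unknown)}")
    kept = [rec for rec in cs if policy.retains(rec.support, rec.svlen)]
    return Callset(cs.label, kept, dict(cs.meta)).sort()


@dataclass
class IntegrationAudit:
    """Per-stage record counts; conservation: input == kept + removed."""

    rows: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_kept: int) -> None:
        self.rows.append(
            {"stage": stage, "input": n_in, "kept": n_kept, "removed": n_in - n_kept}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "input", "kept", "removed"])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_high_confidence(
    callsets,
    excl: RegionSet | None = None,
    match_params: MatchParams = SVMERGE_DEFAULT,
    policy: RetentionPolicy = RetentionPolicy(),
    priority=PLATFORMS,
    audit_path: str | None = None,
) -> tuple[Callset, IntegrationAudit]:
    """cluster_merge -> filter_excluded_regions -> apply_retention_rules.

    Returns the high-confidence callset plus a per-stage audit (written as
    TSV when ``audit_path`` is given).
    """
    if len(callsets) < 1:
        raise ValueError("at least one callset required")
    audit = IntegrationAudit()
    merged = cluster_merge(callsets, match_params, priority, label="highconf")
    audit.add("merge", merged.meta.get("n_input", 0), len(merged))
    if excl is not None and len(excl):
        kept, _removed = filter_excluded_regions(merged, excl)
    else:
        kept = merged
    audit.add("exclusion_filter", len(merged), len(kept))
    final = apply_retention_rules(kept, policy)
    audit.add("retention_tiers", len(kept), len(final))
    if audit_path is not None:
        audit.write(audit_path)
    return final, audit
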