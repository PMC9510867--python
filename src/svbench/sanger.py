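"""Concordance of Sanger-derived observations with high-confidence SV calls.

The module consumes a pre-extracted table of per-amplicon observations
(chromatogram processing and BLAST alignment of Sanger reads happen
upstream) and applies the manual-curation criteria: an SV event seen in a
Sanger read, the called length matching the observed length within a 10 bp
tolerance, and the called breakpoint matching the observed breakpoint
within the same tolerance. Insertions longer than a single Sanger reaction
can resolve (500 bp) are uncertain in every dimension, and uncertain sites
are excluded from the concordance rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import SVRecord

MATCH, MISMATCH, UNCERTAIN = "match", "mismatch", "uncertain"
DIMENSIONS = ("type", "length", "breakpoint")


@dataclass
class SangerCall:
    """One PCR/Sanger assessment of a targeted high-confidence SV."""

    sv_id: str
    amplified: bool
    sequenced: bool
    observed_type: str = "none"  # DEL / INS / none
    observed_len: int | None = None
    observed_breakpoint: int | None = None
    region_class: str = "intergenic"  # genic / intergenic

    def __post_init__(self):
        if self.sequenced and not self.amplified:
            raise ValueError(f"{self.sv_id}: sequenced implies amplified")
        if not self.sequenced and (
            self.observed_type != "none"
            or self.observed_len is not None
            or self.observed_breakpoint is not None
        ):
            raise ValueError(f"{self.sv_id}: observations present without sequencing")


@dataclass(frozen=True)
class ConcordancePolicy:
    tol: int = 10  # bp tolerance on length and breakpoint
    ins_max_resolvable: int = 500  # longest INS a single Sanger reaction resolves

    def __post_init__(self):
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass
class ConcordanceRecord:
    type: str
    length: str
    breakpoint: str

    def as_dict(self) -> dict:
        return {"type": self.type, "length": self.length, "breakpoint": self.breakpoint}


def classify_concordance(
    sc: SangerCall, sv: SVRecord, pol: ConcordancePolicy = ConcordancePolicy()
) -> ConcordanceRecord:
    """Score one sequenced Sanger call against its targeted SV.

    A dimension is uncertain when its observation is absent, and every
    dimension is uncertain for insertions beyond single-read resolution.
    """
    if sc.sv_id != sv.id:
        raise ValueError(f"Sanger call targets {sc.sv_id}, record is {sv.id}")
    if not sc.sequenced:
        raise ValueError(f"{sc.sv_id}: concordance requires a sequenced call")
    if sv.svtype == "INS" and sv.svlen > pol.ins_max_resolvable:
        return ConcordanceRecord(UNCERTAIN, UNCERTAIN, UNCERTAIN)
    type_res = MATCH if sc.observed_type == sv.svtype else MISMATCH
    if sc.observed_len is None:
        len_res = UNCERTAIN
    else:
        len_res = MATCH if abs(sc.observed_len - sv.svlen) <= pol.tol else MISMATCH
    if sc.observed_breakpoint is None:
        bp_res = UNCERTAIN
    else:
        bp_res = MATCH if abs(sc.observed_breakpoint - sv.start) <= pol.tol else MISMATCH
    return ConcordanceRecord(type_res, len_res, bp_res)


def _rate(num: int, den: int) -> float:
    return num / den if den else 0.0


def aggregate_rates(
    calls,
    results: dict | None = None,
    strata: tuple = ("region_class",),
) -> dict:
    """Amplification / sequencing / concordance rates with their counts.

    ``results`` maps sv_id -> ConcordanceRecord for the sequenced calls;
    concordance rates count matches/(matches+mismatches), uncertain sites
    excluded. Rates are fractions in [0, 1]; counts always ride alongside.
    """
    calls = list(calls)
    results = results or {}

    def amp_block(subset) -> dict:
        assessed = len(subset)
        amplified = sum(1 for c in subset if c.amplified)
        return {"assessed": assessed, "amplified": amplified, "rate": _rate(amplified, assessed)}

    report: dict = {"amplification": {"overall": amp_block(calls)}}
    if "region_class" in strata:
        for cls in sorted({c.region_class for c in calls}):
            report["amplification"][cls] = amp_block(
                [c for c in calls if c.region_class == cls]
            )

    amplified = [c for c in calls if c.amplified]
    sequenced = [c for c in calls if c.sequenced]
    report["sequencing"] = {
        "amplified": len(amplified),
        "sequenced": len(sequenced),
        "rate": _rate(len(sequenced), len(amplified)),
    }

    def conc_block(subset) -> dict:
        block = {}
        for dim in DIMENSIONS:
            statuses = [
                getattr(results[c.sv_id], dim) for c in subset if c.sv_id in results
            ]
            m, mm = statuses.count(MATCH), statuses.count(MISMATCH)
            block[dim] = {
                "matches": m,
                "mismatches": mm,
                "uncertain": statuses.count(UNCERTAIN),
                "rate": _rate(m, m + mm),
            }
        return block

    report["concordance"] = {"overall": conc_block(sequenced)}
    if "region_class" in strata:
        for cls in sorted({c.region_class for c in sequenced}):
            report["concordance"][cls] = conc_block(
                [c for c in sequenced if c.region_class == cls]
            )
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten an aggregate_rates report into a tidy table."""
    rows = []
    for stratum, block in report["amplification"].items():
        rows.append({"section": "amplification", "stratum": stratum, **block})
    rows.append({"section": "sequencing", "stratum": "overall", **report["sequencing"]})
    for stratum, dims in report["concordance"].items():
        for dim, block in dims.items():
            rows.append(
                {"section": f"concordance_{dim}", "stratum": stratum, **block}
            )
    return pd.DataFrame(rows)


_TRUE = {"1", "true", "yes", "y"}


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in _TRUE


def read_sanger_tsv(path: str) -> list:
    """Load SangerCalls from a TSV with the documented columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sv_id", "amplified", "sequenced"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    calls = []
    for _, row in df.iterrows():
        calls.append(
            SangerCall(
                sv_id=row["sv_id"],
                amplified=_to_bool(row["amplified"]),
                sequenced=_to_bool(row["sequenced"]),
                observed_type=row.get("observed_type", "none") or "none",
                observed_len=int(row["observed_len"]) if row.get("observed_len") else None,
                observed_breakpoint=(
                    int(row["observed_breakpoint"]) if row.get("observed_breakpoint") else None
                ),
                region_class=row.get("region_class", "intergenic") or "intergenic",
            )
        )
    return calls
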