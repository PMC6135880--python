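"""Run reports: the human-readable summary and its machine-readable mirror.

Percentages are rounded the way the corresponding published statistics are
printed: viral-family and COG shares as integer percent (one decimal when the
share is below 1%), gene-set shares (ORFan, ortholog sharing, overlap, scan)
at one decimal.  Every printed number also appears, unrounded and rounded, in
the JSON mirror; funnel counts are checked to be non-increasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

from .pipeline import CogSummary, HgtCandidate, TaxonomicSummary

HEADER_NOTES = (
    "taxonomic labels derive from the single best database hit per gene "
    "(no lowest-common-ancestor reconciliation)",
)


def share_pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage of a count pair at the stated printed precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)


def round_family_share(share: float) -> float | int:
    """Family-style share: integer percent at >= 1%, one decimal below."""
    pct = 100.0 * share
    return round(pct) if pct >= 1.0 else round(pct, 1)


def round_one_decimal(share: float) -> float:
    return round(100.0 * share, 1)


@dataclass
class RunReport:
    """Aggregated pipeline outputs ready for printing/serialisation."""

    taxonomy: TaxonomicSummary | None = None
    candidates: list[HgtCandidate] = field(default_factory=list)
    cog: CogSummary | None = None
    overlap: tuple[int, float] | None = None  # (shared count, share %)
    overlap_denominator: int | None = None
    scan_hits: int | None = None
    scan_denominator: int | None = None
    conservation_totals: dict[str, int] | None = None
    direction_calls: dict[str, int] | None = None

    def funnel(self) -> dict[str, int]:
        cands = self.candidates
        counts = {
            "viral_best_hit": len(cands),
            "length_gt_100": sum(1 for c in cands if c.length_ge_100),
            "context_pass": sum(
                1 for c in cands if c.length_ge_100 and c.scaffold_context_pass
            ),
            "rescreened": sum(1 for c in cands if c.rescreen_pattern is not None),
            "direction_tested": sum(1 for c in cands if c.direction != "untested"),
        }
        stages = list(counts.values())
        assert all(a >= b for a, b in zip(stages, stages[1:])), "funnel must be non-increasing"
        return counts

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"notes": list(HEADER_NOTES), "funnel": self.funnel()}
        if self.taxonomy is not None:
            t = self.taxonomy
            assert abs(sum(t.category_proportions.values()) - 1.0) < 1e-9
            out["taxonomy"] = {
                "n_genes": t.n_genes,
                "category_counts": t.category_counts,
                "category_pct": {
                    c: round_family_share(p) for c, p in t.category_proportions.items()
                },
                "family_counts": t.family_counts,
                "family_share_pct": {
                    f: round_family_share(s) for f, s in t.family_shares.items()
                },
            }
            orfan = t.category_proportions.get("ORFan", 0.0)
            out["taxonomy"]["orfan_share_pct"] = round_one_decimal(orfan)
        if self.cog is not None:
            out["cog"] = {
                "counts": self.cog.counts,
                "share_pct": self.cog.shares_pct,
                "n_assigned": self.cog.n_assigned,
                "n_unassigned": self.cog.n_unassigned,
            }
        if self.overlap is not None:
            shared, share_pct = self.overlap
            out["overlap"] = {
                "shared": shared,
                "share_pct": share_pct,
                "denominator": self.overlap_denominator,
            }
        if self.scan_hits is not None:
            out["scan"] = {"hits": self.scan_hits}
            if self.scan_denominator:
                out["scan"]["share_pct"] = round_one_decimal(
                    self.scan_hits / self.scan_denominator
                )
        if self.conservation_totals is not None:
            out["conservation_totals"] = self.conservation_totals
        if self.direction_calls is not None:
            out["direction_calls"] = self.direction_calls
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = ["# amoebahgt run report"]
        for note in d["notes"]:
            lines.append(f"# note: {note}")
        if "taxonomy" in d:
            t = d["taxonomy"]
            lines.append(f"genes: {t['n_genes']}")
            lines.append("category shares (%): " + ", ".join(
                f"{c}={t['category_pct'][c]}" for c in sorted(t["category_pct"])
            ))
            lines.append(f"ORFan share: {t['orfan_share_pct']}%")
            if t["family_share_pct"]:
                lines.append("viral family shares (% of viral-labeled genes): " + ", ".join(
                    f"{f}={t['family_share_pct'][f]}" for f in sorted(t["family_share_pct"])
                ))
        lines.append("candidate funnel: " + " -> ".join(
            f"{k}={v}" for k, v in d["funnel"].items()
        ))
        if "cog" in d:
            lines.append("COG shares (%): " + ", ".join(
                f"{c}={d['cog']['share_pct'][c]}" for c in sorted(d["cog"]["share_pct"])
            ))
        if "overlap" in d:
            o = d["overlap"]
            lines.append(f"overlap with reference gene set: {o['shared']} ({o['share_pct']}%)")
        if "scan" in d:
            s = d["scan"]
            extra = f" ({s['share_pct']}% of screened genes)" if "share_pct" in s else ""
            lines.append(f"genome-scan viral homolog loci: {s['hits']}{extra}")
        if "conservation_totals" in d:
            lines.append("conserved viral genes per genome: " + ", ".join(
                f"{g}={n}" for g, n in sorted(d["conservation_totals"].items())
            ))
        if "direction_calls" in d:
            lines.append("direction calls: " + ", ".join(
                f"{k}={v}" for k, v in sorted(d["direction_calls"].items())
            ))
        return "\n".join(lines) + "\n"
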