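"""Text report generation in the study's table layout."""
from __future__ import annotations

import pandas as pd

SCAN_HEADER = ["Outcome", "Gene", "Contrast", "N", "n", "%", "HR", "95% CI", "P", "FDR P"]


def format_scan_table(results: pd.DataFrame) -> str:
    """Per-outcome association tables: Outcome Gene Allele N n % HR 95% CI P."""
    if results.empty:
        return "\t".join(SCAN_HEADER)
    lines = ["\t".join(SCAN_HEADER)]
    for _, row in results.iterrows():
        ci = f"{row['ci_low']:.2f}-{row['ci_high']:.2f}"
        lines.append(
            "\t".join(
                [
                    str(row["outcome"]),
                    str(row["gene"]),
                    f"{row['rsid']} {row['contrast']}",
                    str(row["n_at_risk"]),
                    str(row["n_events"]),
                    f"{100 * row['n_events'] / max(row['n_at_risk'], 1):.1f}",
                    f"{row['hr']:.2f}",
                    ci,
                    f"{row['p']:.3g}",
                    f"{row['fdr_p']:.3g}",
                ]
            )
        )
    return "\n".join(lines)


def report_tables(
    scan_results: pd.DataFrame,
    twist_reports: dict[str, str] | None = None,
    impact_lines: list[str] | None = None,
) -> str:
    """Combined run report: scan tables, TWIST suites, impact summary."""
    parts = ["ASSOCIATION SCAN", "=" * 16, format_scan_table(scan_results), ""]
    for key, rep in (twist_reports or {}).items():
        parts += [f"TWIST: {key}", "=" * (7 + len(key)), rep, ""]
    if impact_lines:
        parts += ["POPULATION IMPACT", "=" * 17, *impact_lines, ""]
    return "\n".join(parts)
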