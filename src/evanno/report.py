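"""Filtered result tables and normalized tissue-expression summaries.

The result table applies a conjunction of per-channel thresholds to the
ranked, scored variants.  Defaults (sift 0.05, polyphen 0.85, gmaf 1,
pubmed 0, cosmic 0, disassociation 0, census 0) reduce to the damage
predicate plus the functional-focus match: gmaf = 1 is the documented
no-op sentinel since every real minor allele frequency is <= 0.5, and the
count thresholds at 0 are vacuous.

Census modes partition cleanly: 1 keeps cancer gene census members, 2
keeps interactors of census genes that are not themselves members, and 3
is exactly the union of the two.

The expression summary divides each gene's tissue profile by its own mean
so rows are comparable across genes of very different absolute expression;
every emitted row has mean 1 by construction.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from evanno.refdata import FocusConfig, GeneEvidence
from evanno.scoring import ScoredVariant, match_disease, match_function, write_scored_tsv

logger = logging.getLogger("evanno")


@dataclass
class FilterThresholds:
    """Result-table thresholds; the defaults keep damage + focus only."""

    sift: float = 0.05        # keep when present SIFT <= sift
    polyphen: float = 0.85    # keep when present PolyPhen >= polyphen
    gmaf: float = 1.0         # keep when GMAF absent or <= gmaf (1 = no-op)
    pubmed: int = 0           # keep when literature count >= pubmed
    cosmic: int = 0           # keep when raw COSMIC entry count >= cosmic
    disassociation: int = 0   # keep when focus-matching disease links >= this
    census: int = 0           # 0 any, 1 census, 2 interactor-only, 3 either

    def __post_init__(self) -> None:
        if not 0.0 <= self.sift <= 1.0 or not 0.0 <= self.polyphen <= 1.0:
            raise ValueError("sift and polyphen thresholds must lie in [0, 1]")
        if not 0.0 < self.gmaf <= 1.0:
            raise ValueError(f"gmaf threshold must lie in (0, 1], got {self.gmaf}")
        if min(self.pubmed, self.cosmic, self.disassociation) < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.census not in (0, 1, 2, 3):
            raise ValueError(f"census mode must be 0..3, got {self.census}")


def _damage_ok(sv: ScoredVariant, t: FilterThresholds, mode: str) -> bool:
    sift = sv.enriched.annotation.sift
    polyphen = sv.enriched.annotation.polyphen
    checks = []
    if sift is not None:
        checks.append(sift <= t.sift)
    if polyphen is not None:
        checks.append(polyphen >= t.polyphen)
    if not checks:
        return False  # at least one predictor must be present
    return any(checks) if mode == "any" else all(checks)


def result_table(
    scored: Sequence[ScoredVariant],
    focus: FocusConfig,
    thresholds: FilterThresholds | None = None,
    damage_mode: str = "all",
) -> list[ScoredVariant]:
    """Filter ranked variants; every predicate must hold for retention.

    ``damage_mode`` 'all' (default) requires every *present* damage
    predictor to meet its threshold; 'any' accepts when one does.
    Rank order of the input is preserved in the output.
    """
    t = thresholds or FilterThresholds()
    if damage_mode not in ("all", "any"):
        raise ValueError(f"damage_mode must be 'all' or 'any', got {damage_mode!r}")
    out: list[ScoredVariant] = []
    for sv in scored:
        ann, ev = sv.enriched.annotation, sv.enriched.evidence
        if not _damage_ok(sv, t, damage_mode):
            continue
        if ann.gmaf is not None and ann.gmaf > t.gmaf:
            continue
        if ev.pubmed_count < t.pubmed:
            continue
        if ev.cosmic_count < t.cosmic:
            continue
        if match_disease(ev.disease_names, focus.disease_focus) < t.disassociation:
            continue
        if t.census == 1 and not ev.is_census:
            continue
        if t.census == 2 and not (ev.interacts_census and not ev.is_census):
            continue
        if t.census == 3 and not (ev.is_census or ev.interacts_census):
            continue
        if focus.function_focus and not match_function(ev.process_terms,
                                                       focus.function_focus):
            continue
        out.append(sv)
    return out


def heatmap_matrix(
    table: Sequence[ScoredVariant],
    evidence: Mapping[str, GeneEvidence],
) -> tuple[pd.DataFrame, list[str]]:
    """Mean-normalized expression matrix for the result table's genes.

    Returns (matrix, not_found): rows are the table's genes that carry an
    expression profile, ordered by best variant rank and deduplicated;
    each row is divided by its own mean so the row mean is exactly 1.
    Genes without a profile (or with an all-zero profile, where the
    normalization is undefined) go to ``not_found`` instead of being
    zero-filled.
    """
    seen: set[str] = set()
    genes: list[str] = []
    for sv in table:  # table is rank-ordered
        g = sv.gene_symbol
        if g not in seen:
            seen.add(g)
            genes.append(g)
    rows: dict[str, dict[str, float]] = {}
    not_found: list[str] = []
    for g in genes:
        ev = evidence.get(g)
        profile = ev.expression if ev else None
        if not profile:
            not_found.append(g)
            continue
        mean = sum(profile.values()) / len(profile)
        if mean == 0:
            logger.warning("gene %s has an all-zero expression row; excluded", g)
            not_found.append(g)
            continue
        rows[g] = {t: v / mean for t, v in profile.items()}
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    if rows:
        matrix = matrix.loc[[g for g in genes if g in rows]]
    return matrix, not_found


def _heatmap_color(value: float, vmin: float, vmax: float) -> str:
    # red (lowest) through black to bright green (highest)
    if vmax <= vmin:
        frac = 0.5
    else:
        frac = (value - vmin) / (vmax - vmin)
    red = int(round(255 * max(0.0, 1.0 - 2 * frac)))
    green = int(round(255 * max(0.0, 2 * frac - 1.0)))
    return f"#{red:02x}{green:02x}00"


def render_report(
    table: Sequence[ScoredVariant],
    heatmap: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "report",
    not_found: Sequence[str] = (),
) -> dict[str, Path]:
    """Write the ranked TSV and a static HTML report with a colored heatmap.

    High expression renders bright green, low red.  The TSV is byte-stable
    for a fixed input.  Returns the paths written keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{prefix}.tsv"
    html_path = out_dir / f"{prefix}.html"
    write_scored_tsv(table, tsv_path)

    parts: list[str] = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Ranked variant report</title>",
        "<style>table{border-collapse:collapse;font-family:monospace}"
        "td,th{border:1px solid #999;padding:2px 6px;text-align:right}"
        "th{background:#eee}</style></head><body>",
        "<h1>Ranked variant report</h1>",
        f"<p>{len(table)} variant(s) retained.</p>",
    ]
    tsv_lines = tsv_path.read_text().rstrip("\n").split("\n")
    header, data = tsv_lines[0].split("\t"), tsv_lines[1:]
    parts.append("<table><tr>" + "".join(f"<th>{html.escape(h)}</th>" for h in header)
                 + "</tr>")
    for line in data:
        if not line:
            continue
        parts.append(
            "<tr>" + "".join(f"<td>{html.escape(c)}</td>" for c in line.split("\t"))
            + "</tr>"
        )
    parts.append("</table>")

    parts.append("<h1>Normalized tissue expression</h1>")
    if heatmap.empty:
        parts.append("<p>No result-table gene has an expression profile.</p>")
    else:
        vmin = float(heatmap.values.min())
        vmax = float(heatmap.values.max())
        parts.append("<table><tr><th>gene</th>" + "".join(
            f"<th>{html.escape(str(t))}</th>" for t in heatmap.columns) + "</tr>")
        for gene, row in heatmap.iterrows():
            cells = "".join(
                f"<td style='background:{_heatmap_color(v, vmin, vmax)};"
                f"color:#fff'>{v:.2f}</td>"
                for v in row
            )
            parts.append(f"<tr><th>{html.escape(str(gene))}</th>{cells}</tr>")
        parts.append("</table>")
    if not_found:
        parts.append(
            "<p>No expression profile for: "
            + html.escape(", ".join(not_found)) + "</p>"
        )
    parts.append("</body></html>")
    html_path.write_text("\n".join(parts))
    return {"tsv": tsv_path, "html": html_path}


def render_heatmap_png(heatmap: pd.DataFrame, path: str | Path) -> None:
    """Optional PNG rendering of the normalized expression matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * len(heatmap.columns)), max(2, 0.4 * len(heatmap)))
    )
    im = ax.imshow(heatmap.values, cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(len(heatmap.columns)), heatmap.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(heatmap.index)), heatmap.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="expression / gene mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
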