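"""Static results catalog: downloadable weight files, PheWAS JSON payloads,
SVG Manhattan plots and a self-contained HTML tree (no server required)."""

from __future__ import annotations

import html
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .prs_engine import PrsModel

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogBundle",
    "export_weights",
    "read_weights",
    "export_phewas_json",
    "validate_phewas_payload",
    "render_catalog",
    "plot_manhattan",
]

SCHEMA_PATH = Path(__file__).parent / "schemas" / "phewas_results.schema.json"

_FLOAT_FMT = "%.12g"  # >= 9 significant digits round-trip


@dataclass
class CatalogBundle:
    """Everything the catalog shows for one (trait, PRS method) pair."""

    trait: str
    method_tag: str
    model: PrsModel
    phewas_results: list = field(default_factory=list)
    exclusion_results: list = field(default_factory=list)
    eval_metrics: object | None = None
    alpha: float = 0.05


def export_weights(model: PrsModel, path) -> None:
    """Write the downloadable weight file (TSV); read-back is lossless."""
    df = model.entries.copy()
    df["METHOD_TAG"] = model.method_tag
    df["TRAIT"] = model.trait_label
    cols = ["CHROM", "POS", "ID", "EFFECT_ALLELE", "OTHER_ALLELE", "WEIGHT", "P",
            "METHOD_TAG", "TRAIT"]
    if df.empty:
        logger.warning("exporting empty PRS model to %s", path)
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)
        return
    df[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_weights(path) -> PrsModel:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    method = str(df["METHOD_TAG"].iloc[0]) if len(df) else "external"
    trait = str(df["TRAIT"].iloc[0]) if len(df) else ""
    entries = df.drop(columns=[c for c in ("METHOD_TAG", "TRAIT") if c in df.columns])
    return PrsModel(entries=entries, method_tag=method, trait_label=trait)


def export_phewas_json(results: list, metadata: dict, alpha: float = 0.05) -> dict:
    """JSON payload for the interactive-plot replacement.

    One record per phecode with -log10 p, direction, OR and 95% CI; the
    phenome-wide Bonferroni threshold and PRS provenance ride along. Records
    with undefined p are flagged ``invalid`` rather than dropped.
    """
    if not results:
        raise ValueError("no results to export")
    n = len(results)
    records = []
    for r in results:
        invalid = not np.isfinite(r.p)
        rec = {
            "phecode": str(r.phecode),
            "description": r.description,
            "group": str(r.phecode).split(".")[0],
            "neglog10_p": None if invalid else -math.log10(max(r.p, 5e-324)),
            "direction": r.direction,
            "or": float(np.exp(r.beta_prs)),
            "ci_lower": float(np.exp(r.beta_prs - 1.959963984540054 * r.se)),
            "ci_upper": float(np.exp(r.beta_prs + 1.959963984540054 * r.se)),
            "beta": float(r.beta_prs),
            "se": float(r.se),
            "p": None if invalid else float(r.p),
            "n_case": int(r.n_case),
            "n_control": int(r.n_control),
            "significant": bool(r.bonferroni_significant),
            "invalid": invalid,
        }
        records.append(rec)
    return {
        "metadata": dict(metadata),
        "n_studies": n,
        "alpha": alpha,
        "significance_threshold": alpha / n,
        "results": records,
    }


def _check(cond: bool, msg: str, errors: list) -> None:
    if not cond:
        errors.append(msg)


def validate_phewas_payload(payload: dict) -> list:
    """Validate a PheWAS JSON payload against the shipped schema; returns a
    list of violation messages (empty when valid)."""
    schema = json.loads(SCHEMA_PATH.read_text())
    errors: list = []
    for key in schema["required"]:
        _check(key in payload, f"missing top-level key {key!r}", errors)
    if errors:
        return errors
    _check(isinstance(payload["results"], list) and payload["results"],
           "results must be a non-empty list", errors)
    req = schema["properties"]["results"]["items"]["required"]
    for i, rec in enumerate(payload.get("results", [])):
        for key in req:
            _check(key in rec, f"result {i}: missing key {key!r}", errors)
        if "direction" in rec:
            _check(rec["direction"] in ("up", "down"), f"result {i}: bad direction", errors)
    _check(payload.get("significance_threshold", 0) > 0, "threshold must be positive", errors)
    return errors


def plot_manhattan(results: list, path, alpha: float = 0.05) -> None:
    """Static SVG Manhattan-style plot of -log10 p by phecode group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = sorted(results, key=lambda r: (str(r.phecode).split(".")[0], str(r.phecode)))
    x = np.arange(len(results))
    y = np.array([-math.log10(max(r.p, 5e-324)) if np.isfinite(r.p) else 0.0 for r in results])
    groups = [str(r.phecode).split(".")[0] for r in results]
    colors = [int(g) % 10 if g.isdigit() else sum(map(ord, g)) % 10 for g in groups]
    up = np.array([r.direction == "up" for r in results])
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.scatter(x[up], y[up], c=np.asarray(colors)[up], cmap="tab10", marker="^", s=18)
    ax.scatter(x[~up], y[~up], c=np.asarray(colors)[~up], cmap="tab10", marker="v", s=18)
    if results:
        ax.axhline(-math.log10(alpha / len(results)), color="red", ls="--", lw=1)
    ax.set_xlabel("phecode (grouped by integer part)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:4px 8px}}</style></head>
<body><h1>{title}</h1>
<p><a href="index.html">back to index</a></p>
<p>Weights: <a href="{weights_file}">{weights_file}</a></p>
{metrics_block}
<h2>PheWAS (top hits)</h2>{phewas_table}
{exclusion_block}
<h2>Manhattan plot</h2><img src="{svg_file}" alt="manhattan"/>
<h2>Machine-readable results</h2>
<p><a href="{json_file}">{json_file}</a></p>
<script type="application/json" id="phewas-data">{embedded_json}</script>
</body></html>
"""


def _results_table_html(results: list, limit: int = 20) -> str:
    rows = sorted(results, key=lambda r: (r.p if np.isfinite(r.p) else 2.0))[:limit]
    body = "".join(
        f"<tr><td>{html.escape(str(r.phecode))}</td><td>{html.escape(r.description)}</td>"
        f"<td>{r.n_case}</td><td>{r.odds_ratio:.3f}</td><td>{r.p:.3g}</td>"
        f"<td>{r.direction}</td><td>{'yes' if r.bonferroni_significant else 'no'}</td></tr>"
        for r in rows
    )
    return ("<table><tr><th>phecode</th><th>description</th><th>cases</th><th>OR</th>"
            "<th>p</th><th>direction</th><th>phenome-wide</th></tr>" + body + "</table>")


def render_catalog(bundles: list, outdir) -> list:
    """Write index + one page per (trait, method) with embedded JSON payloads
    and download links; returns the list of written page paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pages = []
    index_items = []
    for b in bundles:
        stem = f"{b.trait}_{b.method_tag}".replace("@", "_at_").replace("/", "_").replace(" ", "_")
        weights_file = f"{stem}.weights.tsv"
        json_file = f"{stem}.phewas.json"
        svg_file = f"{stem}.manhattan.svg"
        export_weights(b.model, outdir / weights_file)
        payload = export_phewas_json(
            b.phewas_results,
            {"trait": b.trait, "method": b.method_tag, "n_variants": len(b.model)},
            alpha=b.alpha,
        )
        (outdir / json_file).write_text(json.dumps(payload, indent=1))
        plot_manhattan(b.phewas_results, outdir / svg_file, alpha=b.alpha)
        if b.exclusion_results:
            excl_block = "<h2>Exclusion PheWAS (top hits)</h2>" + _results_table_html(
                b.exclusion_results
            )
        else:
            excl_block = ""
        if b.eval_metrics is not None:
            e = b.eval_metrics
            metrics_block = (
                f"<h2>Performance</h2><p>AUC {e.auc:.3f} "
                f"[{e.auc_lower:.3f}, {e.auc_upper:.3f}]; Brier {e.brier:.4f}; "
                f"HL p {e.hl_p:.3g}; Nagelkerke R&sup2; {e.nagelkerke_r2:.4f}</p>"
            )
        else:
            metrics_block = ""
        page = outdir / f"{stem}.html"
        page.write_text(
            _PAGE.format(
                title=f"{b.trait} — {b.method_tag}",
                weights_file=weights_file,
                json_file=json_file,
                svg_file=svg_file,
                phewas_table=_results_table_html(b.phewas_results),
                exclusion_block=excl_block,
                metrics_block=metrics_block,
                embedded_json=json.dumps(payload),
            )
        )
        pages.append(page)
        index_items.append(
            f'<li><a href="{page.name}">{html.escape(b.trait)} — '
            f"{html.escape(b.method_tag)}</a></li>"
        )
    index = outdir / "index.html"
    index.write_text(
        "<!DOCTYPE html><html><head><meta charset=\"utf-8\">"
        "<title>PRS-PheWAS catalog</title></head><body>"
        "<h1>PRS-PheWAS catalog</h1><ul>" + "".join(index_items) + "</ul></body></html>"
    )
    return [index] + pages
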