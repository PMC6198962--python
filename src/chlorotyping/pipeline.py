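"""End-to-end orchestration: validated config -> report bundle.

A run consumes either a per-sample digest-call table or aligned region
FASTAs plus a sample sheet, and produces TSV reports (frequencies,
chi-square, AMOVA, discovered sites, network tables), a GraphML export
and a JSON run manifest. Every report embeds the config hash in a
leading ``#`` comment, and a rerun with the same config and inputs is
byte-identical (timestamps go to the log only).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import contingency_table
from .discovery import discover_informative_digests
from .enzymes import default_catalog, load_catalog
from .io import read_sequences
from .networks import eigenvector_centrality, minimum_spanning_network, pairwise_distances
from .panel import (
    ChlorotypePanel,
    DiagnosticSite,
    FOUR_SITE_PANEL,
    TWELVE_SITE_PANEL,
    read_digest_table,
    tabulate_frequencies,
    type_alignments,
)
from .stats import amova, pearson_chisq

__all__ = ["ConfigError", "RunBundle", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

_ANALYSES = ("frequencies", "chisq", "amova", "discover", "network")


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``.errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class RunBundle:
    outdir: Path
    reports: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(cfg: dict) -> str:
    # hash the analytic configuration only: where reports land is not
    # part of what was computed
    cfg = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_panel(spec: str | Path) -> ChlorotypePanel:
    """``4site``/``12site`` or a TSV with columns region, enzyme and an
    optional alignment column."""
    name = str(spec).replace("-", "").lower()
    if name == "4site":
        return FOUR_SITE_PANEL
    if name == "12site":
        return TWELVE_SITE_PANEL
    df = pd.read_csv(spec, sep="\t", dtype=str, keep_default_na=False)
    sites = []
    for _, row in df.iterrows():
        col = row.get("column", "")
        sites.append(
            DiagnosticSite(
                row["region"], row["enzyme"],
                alignment_column=int(col) if col not in ("", None) else None,
            )
        )
    return ChlorotypePanel(Path(spec).stem, tuple(sites))


def validate_config(config: dict | str | Path) -> dict:
    """Check the whole config up front; raises :class:`ConfigError`
    listing every violation before any computation runs."""
    cfg = _load_config(config)
    errors: list[str] = []
    inputs = cfg.get("inputs") or {}
    has_table = "digest_table" in inputs
    has_seqs = "sequences" in inputs
    if not has_table and not has_seqs:
        errors.append("inputs: need 'digest_table' or 'sequences'")
    if has_table and not Path(inputs["digest_table"]).exists():
        errors.append(f"inputs.digest_table: missing path {inputs['digest_table']}")
    if has_seqs:
        for region, path in (inputs["sequences"] or {}).items():
            if not Path(path).exists():
                errors.append(f"inputs.sequences.{region}: missing path {path}")
        sheet = inputs.get("sample_sheet")
        if sheet and not Path(sheet).exists():
            errors.append(f"inputs.sample_sheet: missing path {sheet}")
    analyses = cfg.get("analyses", list(_ANALYSES))
    for a in analyses:
        if a not in _ANALYSES:
            errors.append(f"analyses: unknown analysis {a!r}")
    if "discover" in analyses and not has_seqs:
        errors.append("analyses: 'discover' needs sequence input")
    panel = str(cfg.get("panel", "4site")).replace("-", "").lower()
    if panel not in ("4site", "12site") and not Path(cfg.get("panel", "")).exists():
        errors.append(f"panel: not a shipped panel or readable file: {cfg.get('panel')}")
    enzymes = cfg.get("enzymes")
    if enzymes and not Path(enzymes).exists():
        errors.append(f"enzymes: missing path {enzymes}")
    metric = cfg.get("metric", "hamming")
    if metric not in ("hamming", "nei"):
        errors.append(f"metric: must be hamming or nei, got {metric!r}")
    if int(cfg.get("n_perm", 999)) < 0:
        errors.append("n_perm: must be >= 0")
    if "outdir" not in cfg:
        errors.append("outdir: required")
    if errors:
        raise ConfigError(errors)
    cfg.setdefault("analyses", list(_ANALYSES))
    cfg.setdefault("panel", "4site")
    cfg.setdefault("metric", "hamming")
    cfg.setdefault("n_perm", 999)
    cfg.setdefault("seed", 0)
    return cfg


def _write_tsv(path: Path, frame: pd.DataFrame, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: dict | str | Path) -> RunBundle:
    """Validate, run the requested analyses, and write the report bundle."""
    cfg = validate_config(config)
    cfg_hash = _config_hash(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = RunBundle(outdir)
    log.info("run starting: config hash %s", cfg_hash)

    catalog = load_catalog(cfg["enzymes"]) if cfg.get("enzymes") else default_catalog()
    panel = load_panel(cfg["panel"])
    inputs = cfg["inputs"]

    alignments: dict[str, dict[str, str]] | None = None
    if "digest_table" in inputs:
        dataset, panel = read_digest_table(inputs["digest_table"], panel=None)
    else:
        alignments = {
            region: read_sequences(path) for region, path in inputs["sequences"].items()
        }
        groups = None
        if inputs.get("sample_sheet"):
            sheet = pd.read_csv(inputs["sample_sheet"], sep="\t", dtype=str)
            groups = dict(zip(sheet["sample_id"], sheet["group"]))
        dataset = type_alignments(alignments, panel, catalog, groups=groups)
    log.info("typed %d samples in %d groups on panel %s", len(dataset), len(dataset.groups), panel.name)

    analyses = cfg["analyses"]
    if "frequencies" in analyses:
        freq = tabulate_frequencies(dataset)
        out = freq.counts.copy()
        for g in dataset.groups:
            out[f"{g}_pct"] = freq.percent_rounded[g]
        out.index.name = "chlorotype"
        path = outdir / "frequencies.tsv"
        _write_tsv(path, out, cfg_hash, index=True)
        bundle.reports["frequencies"] = path

    complete = dataset.complete()
    if "chisq" in analyses and len(complete.groups) >= 2:
        rows = []
        tab = contingency_table(complete)
        overall = pearson_chisq(tab)
        rows.append({"comparison": "all-groups", "statistic": overall.statistic,
                     "df": overall.df, "p_value": overall.p_value})
        for a, b in itertools.combinations(complete.groups, 2):
            res = pearson_chisq(tab[[a, b]])
            rows.append({"comparison": f"{a}-vs-{b}", "statistic": res.statistic,
                         "df": res.df, "p_value": res.p_value})
        path = outdir / "chisq.tsv"
        _write_tsv(path, pd.DataFrame(rows), cfg_hash)
        bundle.reports["chisq"] = path

    if "amova" in analyses and len(complete.groups) >= 2:
        res = amova(complete, metric=cfg["metric"], n_perm=int(cfg["n_perm"]),
                    seed=int(cfg["seed"]))
        frame = res.as_frame()
        frame["p_perm"] = [res.p_perm, None, None]
        contrib = pd.DataFrame(
            [{"group": g, "pct_of_ssd_within": v} for g, v in res.within_contributions.items()]
        )
        path = outdir / "amova.tsv"
        _write_tsv(path, frame, cfg_hash)
        path2 = outdir / "amova_within_contributions.tsv"
        _write_tsv(path2, contrib, cfg_hash)
        bundle.reports["amova"] = path
        bundle.reports["amova_within_contributions"] = path2

    if "discover" in analyses and alignments is not None:
        rows = []
        for region, aln in alignments.items():
            for site in discover_informative_digests(aln, catalog, region_id=region, exclude=panel):
                rows.append({"region": site.region_id, "enzyme": site.enzyme,
                             "column": site.alignment_column, "partition": site.partition})
        path = outdir / "discovered_sites.tsv"
        _write_tsv(path, pd.DataFrame(rows, columns=["region", "enzyme", "column", "partition"]),
                   cfg_hash)
        bundle.reports["discovered_sites"] = path

    if "network" in analyses:
        types = sorted({c for c in complete.chlorotypes()})
        freqs = {t: complete.chlorotypes().count(t) for t in types}
        composition: dict[str, dict[str, int]] = {t: {} for t in types}
        for _, g, c in complete.samples:
            composition[c][g] = composition[c].get(g, 0) + 1
        dist = pairwise_distances(types, metric=cfg["metric"])
        net = minimum_spanning_network(dist, node_freqs=freqs, node_composition=composition)
        cent = eigenvector_centrality(net)
        nodes = net.node_table()
        nodes["eigenvector_centrality"] = [cent[n] for n in nodes["chlorotype"]]
        path_e = outdir / "network_edges.tsv"
        _write_tsv(path_e, net.edge_table(), cfg_hash)
        path_n = outdir / "network_nodes.tsv"
        _write_tsv(path_n, nodes, cfg_hash)
        path_g = outdir / "network.graphml"
        net.write_graphml(path_g)
        bundle.reports.update(network_edges=path_e, network_nodes=path_n, network_graphml=path_g)

    bundle.manifest = {
        "tool": "chlorotyping",
        "version": __version__,
        "config": cfg,
        "config_hash": cfg_hash,
        "seed": int(cfg["seed"]),
        "n_samples": len(dataset),
        "groups": dataset.groups,
        "panel": panel.name,
        "reports": {k: str(v) for k, v in bundle.reports.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, default=str) + "\n")
    bundle.reports["manifest"] = manifest_path
    log.info("run finished: %d reports in %s", len(bundle.reports), outdir)
    return bundle
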