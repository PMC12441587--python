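"""End-to-end pipeline: cohort -> states -> edges -> networks -> figures.

``run_pipeline`` reads a cohort CSV, applies the complete-case filter,
classifies health states, estimates all pairwise odds ratios per
transition-group x sex stratum and wave, builds the networks under the
requested weight schemes, computes node strengths and their cross-wave
change, renders figures with CSV sidecars, and writes a JSON manifest
with configuration and input hashes so reruns can be verified byte for
byte against their sidecars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import estimate_all
from .cohort import read_cohort
from .network import (
    build_network,
    network_edge_list,
    node_strength,
    strength_change,
    write_graphml,
)
from .plots import render_network_diagram, render_strength_dotplot
from .states import add_states, build_transition_table, filter_complete_cases

log = logging.getLogger("symptomnet")


@dataclass
class RunConfig:
    """Pipeline parameters (see module docstring)."""

    input: str
    outdir: str
    by: tuple[str, ...] = ("transition", "sex")
    alpha: float = 0.05
    zero_policy: str = "haldane"
    edge_threshold: int = 20
    scheme: str = "both"  # significant_or | or_ratio | both
    gate: str = "above"
    make_figures: bool = True
    figure_strata: tuple[str, ...] | None = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        if self.scheme not in ("significant_or", "or_ratio", "both"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.by = tuple(self.by)
        if self.figure_strata is not None:
            self.figure_strata = tuple(self.figure_strata)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    inp = Path(config.input)
    if not inp.exists():
        raise FileNotFoundError(f"input cohort not found: {inp}")
    outdir = Path(config.outdir)
    (outdir / "nets").mkdir(parents=True, exist_ok=True)
    (outdir / "figs").mkdir(parents=True, exist_ok=True)

    records = read_cohort(inp)
    complete, report = filter_complete_cases(records)
    log.info(
        "complete cases: %d of %d (dropout %.1f%%)",
        report.n_retained, report.n_in, report.dropout_pct,
    )
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": _sha256(inp),
        "n_respondents": int(report.n_in),
        "n_complete": int(report.n_retained),
        "dropout_pct": report.dropout_pct,
    }
    if complete.empty:
        log.warning("no complete cases; writing empty result bundle")
        manifest["empty"] = True
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return manifest

    complete = add_states(complete)
    complete.to_csv(outdir / "states.csv", index=False)

    table = build_transition_table(complete)
    table.to_display().to_csv(outdir / "table1.csv")
    table.counts.to_csv(outdir / "table1_counts.csv")
    table.female_pct.to_csv(outdir / "table1_female_pct.csv")

    edges = estimate_all(
        complete,
        by=config.by,
        alpha=config.alpha,
        zero_policy=config.zero_policy,
    )
    edges.to_csv(outdir / "edges.csv", index=False)

    schemes = (
        ("significant_or", "or_ratio")
        if config.scheme == "both"
        else (config.scheme,)
    )
    strata = sorted(
        edges.groupby(["stratum", "sex"], observed=True).groups
    )

    strength_rows = []
    deltas_rows = []
    n_nets = 0
    for stratum, sex in strata:
        tag = f"{stratum}_{sex}"
        nets = {}
        if "significant_or" in schemes:
            for wave in (6, 8):
                g = build_network(
                    edges, stratum, sex, wave=wave,
                    scheme="significant_or",
                    threshold=config.edge_threshold, gate=config.gate,
                )
                nets[wave] = g
                write_graphml(g, outdir / "nets" / f"{tag}_w{wave}_sig.graphml")
                network_edge_list(g).to_csv(
                    outdir / "nets" / f"{tag}_w{wave}_sig_edges.csv",
                    index=False,
                )
                strength_rows.append(node_strength(g))
                n_nets += 1
            deltas_rows.append(strength_change(nets[6], nets[8]))
        if "or_ratio" in schemes:
            g_ratio = build_network(
                edges, stratum, sex, scheme="or_ratio",
                threshold=config.edge_threshold,
            )
            write_graphml(g_ratio, outdir / "nets" / f"{tag}_ratio.graphml")
            network_edge_list(g_ratio).to_csv(
                outdir / "nets" / f"{tag}_ratio_edges.csv", index=False
            )
            n_nets += 1
            if config.make_figures and (
                config.figure_strata is None or stratum in config.figure_strata
            ):
                render_network_diagram(
                    g_ratio, outdir / "figs" / f"net_{tag}.png"
                )

    if strength_rows:
        strength = pd.concat(strength_rows, ignore_index=True)
        strength.to_csv(outdir / "strength.csv", index=False)
    if deltas_rows:
        deltas = pd.concat(deltas_rows, ignore_index=True)
        deltas.to_csv(outdir / "strength_change.csv", index=False)
        if config.make_figures:
            plot_deltas = (
                deltas
                if config.figure_strata is None
                else deltas[deltas["stratum"].isin(config.figure_strata)]
            )
            if not plot_deltas.empty:
                render_strength_dotplot(
                    plot_deltas, outdir / "figs" / "strength_change.png"
                )

    manifest["n_networks"] = n_nets
    manifest["n_strata"] = len(strata)
    manifest["n_edges_estimated"] = int(len(edges))
    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.suffix in (".csv", ".graphml")
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
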