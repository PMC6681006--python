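"""End-to-end pipeline: normalize -> networks -> cull -> connectivity ->
DE/DW/DS -> enrichment -> report, from one config, with a machine-readable
manifest.

Stage outputs are plain TSV with fixed float formatting and no timestamps,
so two runs with the same inputs, config and seed produce byte-identical
run directories. A network whose connectivity distribution fails the
power-law fit is downgraded to modules-only (its hub/connectivity and
wiring analyses are skipped with a warning) without aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexpression import build_network
from .connectivity import (
    compare_mean_connectivity,
    connectivity_profile,
    cull_network,
    differential_connectivity,
    identify_hubs,
)
from .cosplicing import cosplicing_network, exon_proportions
from .data import read_counts, read_exon_counts, read_gmt
from .difftests import (
    differential_expression,
    differential_splicing,
    differential_wiring,
    differential_wiring_cosplicing,
)
from .enrichment import module_selection_impact
from .normalize import filter_by_cpm, upper_quartile_normalize

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report"]

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Analysis parameters.

    Defaults are the study's printed operating points: mean CPM > 1 for
    inclusion, culling to the genes carrying the top 90% of connectivity,
    minimum module size above 100 genes with ~25 modules targeted, an edge
    change of >= 0.5 for differential wiring, 10,000 permutations,
    FDR < 0.05 for gene-level calls and corrected p < 0.01 for module
    protection.
    """

    counts: str | None = None
    exon_counts: str | None = None
    metadata: str | None = None
    gene_sets: str | None = None
    cpm_threshold: float = 1.0
    keep_fraction: float = 0.90
    min_module_size: int = 100
    target_modules: int = 25
    beta: float | None = 6.0  # None = pick by scale-free criterion
    fit_threshold: float = 0.8
    scale_free_gate: bool = True  # False: run hub analyses even on failure
    delta_threshold: float = 0.5
    n_perm: int = 10_000
    fdr_alpha: float = 0.05
    protection_alpha: float = 0.01
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_name: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage the config's inputs allow and write a run directory.

    Without an exon-count path the cosplicing/DS stages are skipped and all
    else completes. Returns the run directory path; raises
    :class:`PipelineError` naming the failing stage, after recording the
    completed stages in ``checkpoint.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    done: list[str] = []
    manifest: dict = {
        "selnet_version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "inputs": {},
        "stages": {},
    }
    for key in ("counts", "exon_counts", "metadata", "gene_sets"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    def checkpoint(stage: str) -> None:
        done.append(stage)
        (out / "checkpoint.json").write_text(
            json.dumps({"completed_stages": done}, indent=2, sort_keys=True) + "\n"
        )

    flagged_sets: dict[str, set] = {}
    stage = "ingest"
    try:
        if config.counts is None or config.metadata is None:
            raise ValueError("counts and metadata paths are required")
        cm = read_counts(config.counts, config.metadata)
        checkpoint(stage)

        stage = "normalize"
        ne = filter_by_cpm(upper_quartile_normalize(cm), config.cpm_threshold)
        ne.write(out / "normalized_log2cpm.tsv", out / "scale_factors.tsv")
        manifest["stages"][stage] = {"n_genes_kept": len(ne.gene_ids)}
        checkpoint(stage)

        stage = "coexpression"
        from .coexpression import correlation_matrix

        corr_by_line = {
            line: correlation_matrix(ne, line) for line in ("HIGH", "LOW")
        }
        net = build_network(
            corr_by_line,
            beta=config.beta,
            fit_threshold=config.fit_threshold,
            min_module_size=config.min_module_size,
            target_module_count=config.target_modules,
        )
        _write_tsv(net.modules.rename("module").to_frame(),
                   out / "modules_coexpression.tsv")
        fit_rows = pd.DataFrame(
            {
                ln: {"r_squared": f.r_squared, "slope": f.slope,
                     "passes": f.passes}
                for ln, f in net.fit_by_line.items()
            }
        ).T
        _write_tsv(fit_rows, out / "scale_free_fit_coexpression.tsv", "line")
        manifest["stages"][stage] = {
            "beta": net.beta,
            "n_modules": int((net.modules != "grey").sum() and
                             net.modules[net.modules != "grey"].nunique()),
            "scale_free_ok": bool(net.scale_free_ok),
        }
        checkpoint(stage)

        stage = "cull"
        k_by_line = {
            ln: adj.to_numpy().sum(axis=1) - 1.0
            for ln, adj in net.adjacency_by_line.items()
        }
        k_summed = pd.Series(sum(k_by_line.values()), index=net.consensus.index)
        kept = cull_network(k_summed, config.keep_fraction)
        pd.Series(sorted(kept), name="gene_id").to_csv(
            out / "culled_genes.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {"n_kept": len(kept)}
        checkpoint(stage)

        stage = "connectivity"
        hub_ok = net.scale_free_ok or not config.scale_free_gate
        if hub_ok:
            cts = {}
            for ln in ("HIGH", "LOW"):
                adj = net.adjacency_by_line[ln].loc[kept, kept]
                ct = connectivity_profile(adj, net.modules, ln)
                cts[ln] = identify_hubs(ct)
            conn = pd.concat(cts.values())
            _write_tsv(conn, out / "connectivity.tsv")
            dc = differential_connectivity(
                cts["HIGH"], cts["LOW"], config.delta_threshold
            )
            _write_tsv(dc, out / "differential_connectivity.tsv")
            comp_rows = []
            for scope in ("total", "modular"):
                mh, ml, p = compare_mean_connectivity(
                    cts["HIGH"], cts["LOW"], scope
                )
                comp_rows.append(
                    {"scope": scope, "mean_high": mh, "mean_low": ml, "p": p}
                )
            pd.DataFrame(comp_rows).to_csv(
                out / "connectivity_comparison.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT,
            )
            manifest["stages"][stage] = {"skipped": False}
        else:
            log.warning("scale-free fit failed; skipping hub/connectivity "
                        "analyses for the coexpression network")
            manifest["stages"][stage] = {
                "skipped": True,
                "reason": "scale-free fit failed; modules retained, "
                          "hub/connectivity analyses skipped",
            }
        checkpoint(stage)

        stage = "differential_expression"
        de = differential_expression(ne)
        _write_tsv(de, out / "de.tsv")
        flagged_sets["DE"] = set(de.index[de["fdr"] < config.fdr_alpha])
        manifest["stages"][stage] = {"n_de": len(flagged_sets["DE"])}
        checkpoint(stage)

        stage = "differential_wiring"
        if hub_ok:
            kept_sorted = [g for g in ne.gene_ids if g in set(kept)]
            dw = differential_wiring(
                ne.log2cpm.loc[kept_sorted, ne.samples_of("HIGH")],
                ne.log2cpm.loc[kept_sorted, ne.samples_of("LOW")],
                config.delta_threshold,
                config.n_perm,
                seed=config.seed,
            )
            _write_tsv(dw, out / "dw.tsv")
            flagged_sets["DW"] = set(dw.index[dw["fdr"] < config.fdr_alpha])
            manifest["stages"][stage] = {
                "n_dw": len(flagged_sets["DW"]),
                "mean_changed_edges": float(dw["changed_edge_count"].mean()),
            }
        else:
            manifest["stages"][stage] = {"skipped": True}
        checkpoint(stage)

        if config.exon_counts:
            stage = "cosplicing"
            ect = read_exon_counts(config.exon_counts, config.metadata)
            profiles = exon_proportions(ect)
            cnet = cosplicing_network(
                profiles, ect.meta,
                beta=config.beta,
                fit_threshold=config.fit_threshold,
                min_module_size=config.min_module_size,
                target_module_count=config.target_modules,
            )
            _write_tsv(cnet.modules.rename("module").to_frame(),
                       out / "modules_cosplicing.tsv")
            manifest["stages"][stage] = {
                "beta": cnet.beta, "scale_free_ok": bool(cnet.scale_free_ok)
            }
            checkpoint(stage)

            stage = "differential_splicing"
            ds = differential_splicing(
                profiles, ect.meta, config.n_perm, seed=config.seed + 1
            )
            _write_tsv(ds, out / "ds.tsv")
            flagged_sets["DS"] = set(ds.index[ds["fdr"] < config.fdr_alpha])
            manifest["stages"][stage] = {"n_ds": len(flagged_sets["DS"])}
            checkpoint(stage)

            stage = "differential_wiring_cosplicing"
            if cnet.scale_free_ok or not config.scale_free_gate:
                dwc = differential_wiring_cosplicing(
                    profiles, ect.meta, config.delta_threshold,
                    config.n_perm, seed=config.seed + 2,
                )
                _write_tsv(dwc, out / "dw_cosplicing.tsv")
                manifest["stages"][stage] = {
                    "n_dw_cosplicing": int((dwc["fdr"] < config.fdr_alpha).sum())
                }
            else:
                log.warning("cosplicing scale-free fit failed; skipping "
                            "cosplicing wiring analysis")
                manifest["stages"][stage] = {"skipped": True}
            checkpoint(stage)

        stage = "enrichment"
        universe = set(kept)
        enr_frames = []
        for name, genes in flagged_sets.items():
            tbl = module_selection_impact(
                net.modules, genes, universe,
                alpha=config.protection_alpha, set_name=name,
            )
            enr_frames.append(tbl)
        if config.gene_sets:
            for name, genes in sorted(read_gmt(config.gene_sets).items()):
                enr_frames.append(
                    module_selection_impact(
                        net.modules, genes, universe,
                        alpha=config.protection_alpha, set_name=name,
                    )
                )
        if enr_frames:
            _write_tsv(pd.concat(enr_frames), out / "enrichment.tsv", "module")
        manifest["stages"][stage] = {"n_sets": len(enr_frames)}
        checkpoint(stage)
    except Exception as exc:  # noqa: BLE001 - named-stage reporting
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    write_report(out)
    return out


def write_report(run_dir) -> Path:
    """Summarize a completed (or partial) run into one TSV and one text file.

    Regeneration is idempotent; missing stage outputs appear as explicit
    gaps rather than errors.
    """
    run = Path(run_dir)
    rows = []

    def add(metric: str, value) -> None:
        rows.append({"metric": metric, "value": value})

    manifest_path = run / "manifest.json"
    if manifest_path.exists():
        stages = json.loads(manifest_path.read_text()).get("stages", {})
        for stage_name, info in sorted(stages.items()):
            for k, v in sorted(info.items()):
                add(f"{stage_name}.{k}", v)
    for fname, metric in [
        ("de.tsv", "n_de_fdr05"), ("dw.tsv", "n_dw_fdr05"),
        ("ds.tsv", "n_ds_fdr05"),
    ]:
        path = run / fname
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            add(metric, int((df["fdr"] < 0.05).sum()))
        else:
            add(metric, "not run")
    conn = run / "connectivity_comparison.tsv"
    if conn.exists():
        for _, r in pd.read_csv(conn, sep="\t").iterrows():
            add(f"mean_k_{r['scope']}_high", r["mean_high"])
            add(f"mean_k_{r['scope']}_low", r["mean_low"])
    enr = run / "enrichment.tsv"
    if enr.exists():
        df = pd.read_csv(enr, sep="\t")
        add("n_modules_enriched", int((df["call"] == "enriched").sum()))
        add("n_modules_protected", int((df["call"] == "protected").sum()))

    report = pd.DataFrame(rows)
    report.to_csv(run / "report.tsv", sep="\t", index=False)
    lines = ["selnet run summary", "==================", ""]
    lines += [f"{r['metric']}: {r['value']}" for r in rows]
    (run / "report.txt").write_text("\n".join(lines) + "\n")
    return run / "report.tsv"
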