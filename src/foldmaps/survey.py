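"""End-to-end survey driver: fold a family of potentials at one chain
length and collect per-map and cross-map artifacts.

The protocol per potential is: enumerate sequences, fold each onto every
contact set, derive the map summaries (non-degeneracy nu, encodability c,
median foldability), decompose the viable graph, and run the distribution
reports. Across potentials it assembles Jaccard similarity matrices
(genotype and phenotype space), group-average/single/complete dendrograms,
the summary table, and the set of phenotypes encoded by every potential.

A survey directory is resumable: a manifest records the configuration
hash, per-potential artifacts are skipped when already present, and a run
against a directory written with a different configuration is refused.
Results are worker-count-invariant (potentials are processed
independently and gathered in input order).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .folding import MapResult, PairCountCache, fold_map_many
from .graphs import build_and_decompose, expected_size
from .lattice import ContactInventory, enumerate_conformations
from .potentials import (
    BinaryPotential,
    grid_sample,
    natural_binary_potentials,
    read_potentials_csv,
)
from .stats import cluster_maps, compactness_report, compositional_report, jaccard

__all__ = ["SurveyConfig", "run_survey", "audit_survey"]


@dataclass
class SurveyConfig:
    L: int = 10
    potentials: str = "grid"  # "grid" | "mj-binary" | path to CSV
    replicates: int = 20
    seed: int = 1
    outdir: str = "survey"
    n_workers: int = 1
    encodability_denominator: str = "unique"
    with_reports: bool = True
    linkage_methods: tuple = ("average",)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k not in ("outdir", "n_workers")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=list).encode()).hexdigest()[:16]


def _resolve_potentials(source: str):
    if source == "grid":
        return grid_sample()
    if source == "mj-binary":
        from .fixtures import load_contact_table

        names, m = load_contact_table()
        pots, _ = natural_binary_potentials(m, names)
        return pots
    return read_potentials_csv(source)


def _fold_one(inv, p, cfg, pdir):
    res = next(iter(fold_map_many(inv, [p], encodability_denominator=cfg.encodability_denominator)))
    dec = build_and_decompose(res)
    row = res.summary() | dec.summary()
    pdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        pdir / "records.npz",
        E_min_scaled=res.E_min_scaled,
        degeneracy=res.degeneracy,
        native_idx=res.native_idx,
        foldability=res.foldability,
        energy_scale=res.energy_scale,
    )
    if cfg.with_reports:
        comp = compositional_report(res, cfg.replicates, cfg.seed)
        compact = compactness_report(res, inv, cfg.replicates, cfg.seed)
        comp.to_frame().to_csv(pdir / "compositional.csv", index=False)
        compact.to_frame().to_csv(pdir / "compactness.csv", index=False)
    nets = pd.DataFrame(
        [
            {k: v for k, v in n.items() if k != "codes"}
            for n in dec.networks
        ]
    )
    nets.to_csv(pdir / "neutral_networks.csv", index=False)
    (pdir / "summary.json").write_text(json.dumps(row, indent=2))
    return row, res


def run_survey(config: SurveyConfig):
    """Run (or resume) a survey; returns the summary DataFrame."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    digest = cfg.digest()
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev["digest"] != digest:
            raise RuntimeError(
                "survey directory was written with a different configuration; "
                "refusing to mix artifacts"
            )
    else:
        manifest_path.write_text(json.dumps({"digest": digest, "config": asdict(cfg)}, indent=2, default=list))

    cache_path = out / f"inventory_L{cfg.L}.npz"
    if cache_path.exists():
        inv = ContactInventory.load(cache_path)
    else:
        inv = enumerate_conformations(cfg.L)
        inv.save(out / f"inventory_L{cfg.L}")

    potentials = _resolve_potentials(cfg.potentials)
    rows = []
    maps: list[MapResult] = []

    def pot_dir(i, p):
        return out / "potentials" / f"{i:03d}"

    todo = []
    for i, p in enumerate(potentials):
        pdir = pot_dir(i, p)
        if (pdir / "summary.json").exists():
            rows.append(json.loads((pdir / "summary.json").read_text()))
            maps.append(None)
        else:
            todo.append((i, p))
            rows.append(None)
            maps.append(None)

    if todo:
        if cfg.n_workers > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=cfg.n_workers)(
                delayed(_fold_one)(inv, p, cfg, pot_dir(i, p)) for i, p in todo
            )
        else:
            results = [_fold_one(inv, p, cfg, pot_dir(i, p)) for i, p in todo]
        for (i, _), (row, res) in zip(todo, results):
            rows[i] = row
            maps[i] = res

    # reload any maps skipped by resume (needed for cross-map artifacts)
    for i, p in enumerate(potentials):
        if maps[i] is None:
            with np.load(pot_dir(i, p) / "records.npz") as z:
                maps[i] = MapResult(
                    inventory=inv,
                    potential=p,
                    E_min_scaled=z["E_min_scaled"],
                    degeneracy=z["degeneracy"],
                    native_idx=z["native_idx"],
                    foldability=z["foldability"],
                    energy_scale=int(z["energy_scale"]),
                    encodability_denominator=cfg.encodability_denominator,
                )

    summary = pd.DataFrame(rows)
    summary.insert(0, "index", np.arange(len(potentials)))
    summary.to_csv(out / "summary.csv", index=False)

    n = len(maps)
    for space in ("genotype", "phenotype"):
        J = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                J[i, j] = J[j, i] = jaccard(maps[i], maps[j], space)
        labels = [p.label or str(i) for i, p in enumerate(potentials)]
        pd.DataFrame(J, index=labels, columns=labels).to_csv(out / f"jaccard_{space}.csv")
        if n >= 2:
            for method in cfg.linkage_methods:
                dg = cluster_maps(J, method=method, labels=labels, metadata=summary)
                (out / f"dendrogram_{space}_{method}.nwk").write_text(dg.newick())

    universal = None
    for m in maps:
        x = set(m.X.tolist())
        universal = x if universal is None else universal & x
    (out / "cross_map.json").write_text(
        json.dumps(
            {
                "n_potentials": n,
                "universal_phenotypes": len(universal or set()),
                "nu_range": [float(summary["nu"].min()), float(summary["nu"].max())],
                "c_range": [float(summary["c"].min()), float(summary["c"].max())],
                "median_foldability_range": [
                    float(summary["median_foldability"].min()),
                    float(summary["median_foldability"].max()),
                ],
            },
            indent=2,
        )
    )
    return summary


def audit_survey(outdir) -> bool:
    """Recompute nu and c of every potential from its persisted per-sequence
    records and compare with the summary table. Returns True when
    consistent; raises on mismatch."""
    out = Path(outdir)
    summary = pd.read_csv(out / "summary.csv")
    manifest = json.loads((out / "manifest.json").read_text())
    L = manifest["config"]["L"]
    inv = ContactInventory.load(out / f"inventory_L{L}.npz")
    denom = manifest["config"].get("encodability_denominator", "unique")
    n_unique = inv.n_unique if denom == "unique" else inv.n_contact_sets
    for _, row in summary.iterrows():
        with np.load(out / "potentials" / f"{int(row['index']):03d}" / "records.npz") as z:
            viable = z["degeneracy"] == 1
            nu = viable.mean()
            c = len(np.unique(z["native_idx"][viable])) / n_unique
        if not (np.isclose(nu, row["nu"]) and np.isclose(c, row["c"])):
            raise RuntimeError(f"audit mismatch for potential {row['index']}")
    return True
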