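"""Parameter sweeps with replicates, fitting against target maps, outputs.

A sweep runs the simulator over a grid of (mode, d, d_s, P_s) combinations,
each repeated ``replicates`` times with deterministically derived seeds,
builds a replicate-averaged predicted richness map per comparison epoch,
fits each against the observed map and ranks the combinations by summed
BIC.  With an output directory the sweep is resumable: completed runs are
recorded in a JSON manifest and their maps reloaded instead of recomputed,
which never changes any numeric output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landscape import PaleoLandscape, read_landscape
from .simulate import SimConfig, SimResult, SpeciesCapExceeded, run_simulation
from .summaries import ModelFit, model_fit, rank_models

__all__ = [
    "ComparisonTarget",
    "SweepSpec",
    "SweepResult",
    "per_run_seed",
    "run_sweep",
    "write_outputs",
]


@dataclass(frozen=True)
class ComparisonTarget:
    """An observed map to fit against: label, epoch and cell values."""

    label: str
    age_ma: float
    observed: pd.Series  # cell_id -> value


@dataclass
class SweepSpec:
    landscape: PaleoLandscape | str | Path
    targets: tuple[ComparisonTarget, ...]
    modes: tuple[str, ...] = ("parapatric",)
    d_values: tuple[float, ...] = (4.0,)
    ds_values: tuple[float, ...] = (5.0,)
    ps_values: tuple[float, ...] = (6e-5,)
    replicates: int = 20
    base_seed: int = 0
    out_dir: str | Path | None = None
    base_config: SimConfig = field(default_factory=SimConfig)
    per_replicate_fits: bool = False

    def combinations(self) -> list[SimConfig]:
        combos = []
        for mode in self.modes:
            if mode == "parapatric":
                grid = [(d, ds, None) for d in self.d_values for ds in self.ds_values]
            elif mode == "sympatric":
                grid = [(d, None, ps) for d in self.d_values for ps in self.ps_values]
            else:
                grid = [
                    (d, ds, ps)
                    for d in self.d_values
                    for ds in self.ds_values
                    for ps in self.ps_values
                ]
            for d, ds, ps in grid:
                combos.append(
                    replace(
                        self.base_config,
                        mode=mode,
                        d=d,
                        d_s=ds,
                        p_s=ps,
                        snapshot_ages=tuple(sorted({t.age_ma for t in self.targets}, reverse=True)),
                    )
                )
        return combos


def combo_label(cfg: SimConfig) -> str:
    parts = [cfg.mode, f"d{cfg.d:g}"]
    if cfg.d_s is not None:
        parts.append(f"ds{cfg.d_s:g}")
    if cfg.p_s is not None:
        parts.append(f"ps{cfg.p_s:g}")
    return "_".join(parts)


def per_run_seed(base_seed: int, mode: str, d, d_s, p_s, replicate: int) -> int:
    """Deterministic per-run seed: hash(base_seed, mode, d, d_s, P_s, rep)."""
    key = f"{base_seed}|{mode}|{d}|{d_s}|{p_s}|{replicate}".encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclass
class SweepResult:
    fit_table: pd.DataFrame
    ranking: pd.DataFrame
    manifest: dict

    @property
    def best(self) -> pd.Series:
        return self.ranking.iloc[0]


def _habitat_richness(result: SimResult, landscape: PaleoLandscape, age: float) -> pd.Series:
    """Richness over all habitat cells of the slice (zeros where unoccupied)."""
    support = landscape.slice_at(age).habitat_cells
    return result.richness_map(age, support=support)


def run_sweep(spec: SweepSpec) -> SweepResult:
    landscape = (
        spec.landscape
        if isinstance(spec.landscape, PaleoLandscape)
        else read_landscape(spec.landscape)
    )
    if not spec.targets:
        raise ValueError("sweep needs at least one comparison target")
    out_dir = Path(spec.out_dir) if spec.out_dir is not None else None
    manifest: dict = {}
    manifest_path = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.json"
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())

    fits: dict[str, dict[str, ModelFit]] = {}
    fit_rows = []
    for cfg in spec.combinations():
        label = combo_label(cfg)
        rep_maps: dict[str, list[pd.Series]] = {t.label: [] for t in spec.targets}
        n_ok = 0
        for rep in range(spec.replicates):
            seed = per_run_seed(spec.base_seed, cfg.mode, cfg.d, cfg.d_s, cfg.p_s, rep)
            key = f"{label}_rep{rep}"
            entry = manifest.get(key)
            maps = None
            if entry and entry.get("status") == "ok" and out_dir is not None:
                maps = _load_run_maps(out_dir, key, spec.targets)
            if maps is None:
                run_cfg = replace(cfg, seed=seed)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        result = run_simulation(landscape, run_cfg)
                except SpeciesCapExceeded as exc:
                    manifest[key] = {"status": "failed", "seed": seed, "error": str(exc)}
                    continue
                maps = {
                    t.label: _habitat_richness(result, landscape, t.age_ma)
                    for t in spec.targets
                }
                manifest[key] = {"status": "ok", "seed": seed}
                if out_dir is not None:
                    _save_run_maps(out_dir, key, maps)
            n_ok += 1
            for t in spec.targets:
                rep_maps[t.label].append(maps[t.label])
        if n_ok == 0:
            fit_rows.append(
                {"simulation": label, "mode": cfg.mode, "d": cfg.d, "d_s": cfg.d_s,
                 "p_s": cfg.p_s, "status": "failed", "n_replicates": 0}
            )
            continue
        try:
            by_cmp = {}
            for t in spec.targets:
                stack = pd.concat(rep_maps[t.label], axis=1)
                mean_map = stack.mean(axis=1)
                by_cmp[t.label] = model_fit(mean_map, t.observed, k=cfg.n_parameters)
        except ValueError:
            # e.g. constant predicted map after full extinction
            fit_rows.append(
                {"simulation": label, "mode": cfg.mode, "d": cfg.d, "d_s": cfg.d_s,
                 "p_s": cfg.p_s, "status": "degenerate", "n_replicates": n_ok}
            )
            continue
        fits[label] = by_cmp
        row = {"simulation": label, "mode": cfg.mode, "d": cfg.d, "d_s": cfg.d_s,
               "p_s": cfg.p_s, "status": "ok", "n_replicates": n_ok}
        for cname, f in by_cmp.items():
            row[f"r2_{cname}"] = f.r2
            row[f"bic_{cname}"] = f.bic
        row["total_bic"] = sum(f.bic for f in by_cmp.values())
        fit_rows.append(row)

    if manifest_path is not None:
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if not fits:
        raise RuntimeError("every combination failed; nothing to rank")
    ranking = rank_models(fits)
    fit_table = pd.DataFrame(fit_rows)
    if out_dir is not None:
        fit_table.to_csv(out_dir / "fit_table.csv", index=False)
        ranking.to_csv(out_dir / "ranking.csv", index=False)
    return SweepResult(fit_table=fit_table, ranking=ranking, manifest=manifest)


def _save_run_maps(out_dir: Path, key: str, maps: dict[str, pd.Series]) -> None:
    d = out_dir / "runs"
    d.mkdir(exist_ok=True)
    for label, ser in maps.items():
        ser.rename("value").to_csv(d / f"{key}_{label}.csv")


def _load_run_maps(out_dir: Path, key: str, targets) -> dict[str, pd.Series] | None:
    maps = {}
    for t in targets:
        f = out_dir / "runs" / f"{key}_{t.label}.csv"
        if not f.exists():
            return None
        ser = pd.read_csv(f, index_col=0)["value"]
        ser.index = ser.index.astype(int)
        maps[t.label] = ser
    return maps


# ---------------------------------------------------------------------------
# Standard result writers
# ---------------------------------------------------------------------------


def write_outputs(result: SimResult, out_dir) -> None:
    """Write genealogy, event log, snapshots, richness maps and config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "genealogy.nwk").write_text(result.to_newick() + "\n")
    result.events_frame().to_csv(out_dir / "events.csv", index=False)
    result.steps_frame().to_csv(out_dir / "steps.csv", index=False)
    occupancy = []
    for age in sorted(result.snapshots, reverse=True):
        mat = result.snapshot_matrix(age)
        mat.to_csv(out_dir / f"snapshot_{age:g}Ma.csv")
        rich = result.richness_map(age)
        rich.rename("value").to_csv(out_dir / f"richness_{age:g}Ma.csv")
        for sid, cells in result.snapshots[age].items():
            for c in cells:
                occupancy.append((age, sid, int(c)))
    pd.DataFrame(occupancy, columns=["age_Ma", "species_id", "cell_id"]).to_csv(
        out_dir / "occupancy.csv", index=False
    )
    cfg = {k: v for k, v in vars(result.config).items()}
    cfg["forced_extinctions"] = [list(t) for t in cfg["forced_extinctions"]]
    cfg["snapshot_ages"] = list(cfg["snapshot_ages"])
    if cfg.get("start_region") is not None:
        cfg["start_region"] = list(cfg["start_region"])
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    import numpy, scipy  # noqa: PLC0415

    from . import __version__

    (out_dir / "run_log.txt").write_text(
        f"paleoreef {__version__}\nseed {result.config.seed}\n"
        f"numpy {numpy.__version__}\nscipy {scipy.__version__}\n"
        f"extant {len(result.extant_ids)}\n"
    )
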