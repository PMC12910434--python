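"""End-to-end pipeline orchestration.

A YAML config names an ordered list of stages (synthesis, solving,
measurement, statistics).  ``run_pipeline`` validates the whole config
before any stage runs, executes the stages, writes every artifact under a
per-run output directory, and records a manifest: the config snapshot, the
seeds, the package version, and a SHA-256 digest of every output file.
Deterministic stages reproduce their digests on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import yaml

from . import __version__
from .errors import InvalidParameterError
from .images import save_labels, save_stack

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_synth_nucleus(params, ctx, out: Path, seed: int):
    from .mesh import save_mesh
    from .synthetic import NucleusSpec, make_nucleus_surface

    spec = NucleusSpec(
        volume=params.get("volume", 800.0),
        excess_area_pct=params.get("excess_area_pct", 37.0),
        seed=params.get("seed", seed),
    )
    surf, truth = make_nucleus_surface(spec)
    save_mesh(surf, out / "nucleus.off")
    slim = {k: v for k, v in truth.items() if k not in ("coeffs",)}
    (out / "truth.json").write_text(json.dumps(slim, default=_json_default, indent=1))
    ctx["surface"] = surf
    ctx["truth"] = truth


def _stage_synth_render(params, ctx_all, ctx, out: Path, seed: int):
    from .synthetic import RenderSpec, render_stack

    src = params.get("surface_stage")
    if src not in ctx_all or "surface" not in ctx_all[src]:
        raise InvalidParameterError(f"surface_stage {src!r} has no surface")
    spec = RenderSpec(seed=params.get("seed", seed), noiseless=params.get("noiseless", False))
    stack, truth = render_stack(ctx_all[src]["surface"], spec, params.get("signal", "shell"))
    save_stack(stack, str(out / "stack.tif"))
    ctx["stack"] = stack
    ctx["truth"] = truth


def _stage_synth_monolayer(params, ctx, out: Path, seed: int):
    from .synthetic import make_monolayer

    stack, truth = make_monolayer(
        field=tuple(params.get("field", (60.0, 60.0))),
        base_height=params.get("base_height", 3.0),
        tall_cell_fraction=params.get("tall_cell_fraction", 0.0),
        tall_height=params.get("tall_height", 8.0),
        seed=params.get("seed", seed),
    )
    save_stack(stack, str(out / "monolayer.tif"))
    save_labels(truth["labels"], str(out / "labels.tif"))
    ctx["stack"] = stack
    ctx["truth"] = truth


def _stage_measure_nuclei(params, ctx_all, ctx, out: Path, seed: int):
    from .morphometrics import measure_nuclei

    src = params.get("stack_stage")
    if src not in ctx_all or "stack" not in ctx_all[src]:
        raise InvalidParameterError(f"stack_stage {src!r} has no stack")
    df = measure_nuclei(ctx_all[src]["stack"])
    df.to_csv(out / "nuclei.csv", index=False)
    ctx["records"] = df


def _stage_measure_roughness(params, ctx_all, ctx, out: Path, seed: int):
    from .morphometrics import monolayer_height_map

    src = params.get("stack_stage")
    if src not in ctx_all or "stack" not in ctx_all[src]:
        raise InvalidParameterError(f"stack_stage {src!r} has no stack")
    hm = monolayer_height_map(
        ctx_all[src]["stack"],
        crop_margin=params.get("crop_margin", 2.0),
        downsample=params.get("downsample", 4),
    )
    (out / "roughness.json").write_text(
        json.dumps({"roughness_sd_um": hm.roughness_sd}, indent=1)
    )
    import tifffile

    tifffile.imwrite(out / "height_map.tif", hm.grid.astype(np.float32))
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(hm.grid, cmap="turbo", origin="lower")
    fig.colorbar(im, ax=ax, label="height (µm)")
    ax.set_title(f"roughness SD {hm.roughness_sd:.2f} µm")
    fig.savefig(out / "height_map.png", dpi=110)
    plt.close(fig)
    ctx["roughness_sd"] = hm.roughness_sd


def _stage_solve_drop(params, ctx, out: Path, seed: int):
    from .drop import solve_equilibrium
    from .mesh import save_mesh
    from .scenarios import monolayer_scenario

    sc = monolayer_scenario(
        V_cell0=params.get("V_cell0", 2800.0),
        V_nuc0=params.get("V_nuc0", 800.0),
        A_nuc0=params.get("A_nuc0", 1543.0),
        cell_edge=params.get("cell_edge", 2.0),
        nuc_edge=params.get("nuc_edge", 1.3),
        contact_factor=params.get("contact_factor", 0.85),
        seed=params.get("seed", seed),
    )
    res = solve_equilibrium(
        sc.cfg,
        sc.cell,
        sc.nucleus,
        seed=params.get("seed", seed),
        stage_sweeps=params.get("stage_sweeps", 10),
        inner_maxiter=params.get("inner_maxiter", 150),
    )
    save_mesh(res.nucleus, out / "nucleus.off")
    save_mesh(res.cell, out / "cell.off")
    report = {
        "converged": res.converged,
        "residuals": res.residuals,
        "total_energy": res.total_energy,
        "outer_iterations": res.outer_iterations,
    }
    (out / "residuals.json").write_text(json.dumps(report, default=_json_default, indent=1))
    if not res.converged:
        logger.warning("solve stage did not converge: %s", res.residuals)
    ctx["result"] = res
    ctx["cfg"] = sc.cfg


def _stage_solve_indent(params, ctx_all, ctx, out: Path, seed: int):
    from .drop import Obstacle, indent_with_post
    from .mesh import save_mesh
    from .scenarios import rim_indentation_path

    src = params.get("solve_stage")
    if src not in ctx_all or "result" not in ctx_all[src]:
        raise InvalidParameterError(f"solve_stage {src!r} has no solver result")
    pre = ctx_all[src]["result"]
    cfg = ctx_all[src]["cfg"]
    path = rim_indentation_path(
        pre.nucleus,
        depth=params.get("depth", 2.0),
        post_radius=params.get("post_radius", 0.5),
        withdraw=params.get("withdraw", True),
    )
    obs = Obstacle(
        center_xy=path[0],
        radius=params.get("post_radius", 0.5),
        height=params.get("post_height", 5.0),
        approach_path=path,
    )
    res = indent_with_post(pre, obs, cfg)
    save_mesh(res.nucleus, out / "nucleus_indented.off")
    (out / "residuals.json").write_text(
        json.dumps(
            {"converged": res.converged, "residuals": res.residuals},
            default=_json_default,
            indent=1,
        )
    )
    ctx["result"] = res


def _stage_stats_permutation(params, ctx_all, ctx, out: Path, seed: int):
    from .stats import permutation_test, rank_test_passthrough

    if "csv" in params:
        import pandas as pd

        df = pd.read_csv(params["csv"])
        cond = params.get("condition_column", "condition")
        val = params.get("value_column", "roughness_sd")
        groups = df[cond].unique()
        if len(groups) != 2:
            raise InvalidParameterError("need exactly 2 conditions")
        a = df.loc[df[cond] == groups[0], val].to_numpy()
        b = df.loc[df[cond] == groups[1], val].to_numpy()
    else:
        a = np.asarray(params["group_a"], dtype=float)
        b = np.asarray(params["group_b"], dtype=float)
    res = permutation_test(a, b, n_perm=params.get("n_perm", 10_000), seed=params.get("seed", seed))
    out_data = {
        "observed_diff": res.observed_diff,
        "p_value": res.p_value,
        "n_permutations": res.n_permutations,
        "seed": res.seed,
        "mannwhitney_p": rank_test_passthrough(a, b),
    }
    (out / "stats.json").write_text(json.dumps(out_data, indent=1))
    ctx["stats"] = out_data


_STAGES: Dict[str, Callable] = {
    "synth.nucleus": lambda p, ca, c, o, s: _stage_synth_nucleus(p, c, o, s),
    "synth.render": _stage_synth_render,
    "synth.monolayer": lambda p, ca, c, o, s: _stage_synth_monolayer(p, c, o, s),
    "measure.nuclei": _stage_measure_nuclei,
    "measure.roughness": _stage_measure_roughness,
    "solve.drop": lambda p, ca, c, o, s: _stage_solve_drop(p, c, o, s),
    "solve.indent": _stage_solve_indent,
    "stats.permutation": _stage_stats_permutation,
}


def preflight(config: dict) -> None:
    """Validate the whole config before any stage runs; collect all problems
    into a single error."""
    problems = []
    stages = config.get("stages")
    if not stages:
        problems.append("config has no stages")
    names = set()
    for st in stages or []:
        name = st.get("name")
        kind = st.get("kind")
        if not name:
            problems.append(f"stage without a name: {st}")
        elif name in names:
            problems.append(f"duplicate stage name {name!r}")
        names.add(name)
        if kind not in _STAGES:
            problems.append(f"unknown stage kind {kind!r} (stage {name!r})")
        for key in ("surface_stage", "stack_stage", "solve_stage"):
            ref = (st.get("params") or {}).get(key)
            if ref is not None and ref not in names:
                problems.append(f"stage {name!r}: {key} references unknown stage {ref!r}")
        csv = (st.get("params") or {}).get("csv")
        if csv is not None and not Path(csv).exists():
            problems.append(f"stage {name!r}: missing input file {csv}")
    if problems:
        raise InvalidParameterError("pre-flight failed:\n  " + "\n  ".join(problems))


def run_pipeline(
    config_path: str, out_dir: Optional[str] = None, seed: Optional[int] = None
) -> dict:
    """Execute a staged pipeline and return (and write) its manifest."""
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    preflight(config)
    seed = int(seed if seed is not None else config.get("seed", 0))
    root = Path(out_dir or config.get("out_dir") or (config_path.parent / "run"))
    root.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": config,
        "config_path": str(config_path),
        "seed": seed,
        "version": __version__,
        "stages": [],
    }
    ctx_all: Dict[str, dict] = {}
    for st in config["stages"]:
        name, kind = st["name"], st["kind"]
        params = st.get("params") or {}
        stage_out = root / name
        stage_out.mkdir(parents=True, exist_ok=True)
        ctx: dict = {}
        t0 = time.time()
        logger.info("stage %s (%s) ...", name, kind)
        _STAGES[kind](params, ctx_all, ctx, stage_out, seed)
        ctx_all[name] = ctx
        outputs = {
            str(p.relative_to(root)): _digest(p)
            for p in sorted(stage_out.rglob("*"))
            if p.is_file()
        }
        manifest["stages"].append(
            {
                "name": name,
                "kind": kind,
                "params": params,
                "duration_s": round(time.time() - t0, 3),
                "outputs": outputs,
            }
        )
    (root / "manifest.json").write_text(json.dumps(manifest, default=_json_default, indent=1))
    return manifest
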