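"""Command-line interface, run configuration, validation, and manifests.

Subcommands: synth | simulate | sweep | suppress | perturb | freqtrack |
validate.  All file formats are plain text (TSV matrices and tables); node
indices are 0-based throughout, undirected edges are listed once with
i < j.  Every run writes a manifest recording the configuration, seed and
SHA-256 checksums of its outputs, so reruns are byte-for-byte checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import connectome as cn
from . import experiments as ex
from . import synthetic as sd
from .dynamics import OscillatorConfig, simulate, write_trajectory
from .syncmetrics import HUBS, write_matrix

log = logging.getLogger("hubsync")

__all__ = ["RunConfig", "ValidationError", "run_pipeline", "validate_adjacency", "cli"]


class ValidationError(ValueError):
    """Input validation failure; ``diagnostics`` lists every violation."""

    def __init__(self, path, diagnostics):
        self.diagnostics = list(diagnostics)
        msg = f"{path}: " + "; ".join(self.diagnostics[:5])
        if len(self.diagnostics) > 5:
            msg += f" (+{len(self.diagnostics) - 5} more)"
        super().__init__(msg)


def validate_adjacency(path) -> cn.Connectome:
    """Parse and fully validate an adjacency matrix file.

    Collects *all* violations (non-binary cells, asymmetric pairs, nonzero
    diagonal) with their coordinates before failing, so a malformed file is
    diagnosed in one pass.
    """
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except Exception as err:
        raise ValidationError(path, [f"unreadable as numeric matrix: {err}"])
    diags = []
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        if data.shape[1] == 2:  # edge list form: delegate to the reader
            return cn.read_adjacency(path)
        raise ValidationError(path, [f"not square: shape {data.shape}"])
    bad = np.argwhere(~np.isin(data, (0, 1)))
    for i, j in bad[:20]:
        diags.append(f"non-binary value {data[i, j]:g} at ({i},{j})")
    asym = np.argwhere(data != data.T)
    for i, j in asym[:20]:
        if i < j:
            diags.append(f"asymmetric pair ({i},{j})")
    diag_bad = np.flatnonzero(np.diag(data))
    for i in diag_bad[:20]:
        diags.append(f"nonzero diagonal at ({i},{i})")
    if diags:
        raise ValidationError(path, diags)
    return cn.Connectome(data.astype(np.int8))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see CLI flags of the same names)."""

    adjacency: str
    partition: str
    hubs: str | None = None
    outdir: str = "hubsync_out"
    lambda_grid: tuple[float, ...] = ex.DEFAULT_LAMBDA_GRID
    T: float = 700.0
    tau: float = 300.0
    dt: float = 0.05
    sample_dt: float = 1.0
    n_trials: int = 100
    base_seed: int = 0
    condition: str = "normal"  # normal | hub_suppressed | random_suppressed
    #                            | perturbed:hubs | perturbed:random
    #                            | perturbed:module:<id>
    track_trials: int = 5
    write_rij: bool = False

    def oscillator_config(self) -> OscillatorConfig:
        return OscillatorConfig(T=self.T, tau=self.tau, dt=self.dt,
                                sample_dt=self.sample_dt)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    for name in ("adjacency", "partition"):
        if not Path(getattr(cfg, name)).exists():
            raise ValidationError(getattr(cfg, name), ["file not found"])
    c = validate_adjacency(cfg.adjacency)
    p = cn.read_partition(cfg.partition)
    if p.n_nodes != c.N:
        raise ValidationError(cfg.partition,
                              [f"partition covers {p.n_nodes} nodes, network has {c.N}"])
    if cfg.hubs:
        if not Path(cfg.hubs).exists():
            raise ValidationError(cfg.hubs, ["file not found"])
        p = p.with_hubs(cn.read_hub_list(cfg.hubs))
    return c, p


def _write_sweep_table(path: Path, rec: ex.SweepRecord, p: cn.Partition) -> None:
    mods = [int(m) for m in p.module_ids]
    cols = ["lambda", "r", "r_link"] + [f"r_mod{m}" for m in mods] + ["r_intrahub"]
    with open(path, "w") as fh:
        fh.write(f"# condition={rec.condition} n_trials={rec.n_trials} "
                 f"base_seed={rec.base_seed}\n")
        fh.write("\t".join(cols) + "\n")
        for lam in rec.lambda_grid:
            ens = rec.ensembles[lam]
            row = [f"{lam:g}", f"{ens.r:.6f}", f"{ens.r_link:.6f}"]
            row += [f"{rec.modular[lam].get((m, m), float('nan')):.6f}" for m in mods]
            row.append(f"{rec.modular[lam].get((HUBS, HUBS), float('nan')):.6f}")
            fh.write("\t".join(row) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute one condition end-to-end and write outputs + manifest.

    Returns the manifest dict; raises on any stage failure (the CLI maps
    that to a nonzero exit status).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c, p = _load_inputs(cfg)
    manifest: dict = {"config": {**asdict(cfg)}, "outputs": {}, "n_nodes": c.N,
                      "n_edges": c.n_edges}
    log.info("loaded network N=%d E=%d, condition=%s", c.N, c.n_edges, cfg.condition)

    cond = cfg.condition
    osc = cfg.oscillator_config()
    if cond in ("normal", "hub_suppressed", "random_suppressed"):
        run_c = c
        if cond == "hub_suppressed":
            if p.hubs.size == 0:
                raise ValidationError(cfg.hubs or "<hubs>", ["hub set required"])
            run_c, removed = ex.suppress_edges(c, p.hubs)
            manifest["removed_edges"] = removed
        elif cond == "random_suppressed":
            _, removed = ex.suppress_edges(c, p.hubs)
            run_c = ex.suppress_random_edges(c, removed, seed=cfg.base_seed)
            manifest["removed_edges"] = removed
        rec = ex.run_sweep(run_c, p, cfg.lambda_grid, cfg.n_trials,
                           cfg.base_seed, cfg=osc, condition=cond)
        table = outdir / f"sweep_{cond}.tsv"
        _write_sweep_table(table, rec, p)
        manifest["outputs"]["sweep_table"] = str(table)
        ratios = ex.modularity_ratio(rec)
        ratio_path = outdir / f"modularity_ratio_{cond}.tsv"
        with open(ratio_path, "w") as fh:
            fh.write("# lambda\tintramodular_to_global_ratio\n")
            for lam, v in ratios.items():
                fh.write(f"{lam:g}\t{v:.6f}\n")
        manifest["outputs"]["modularity_ratio"] = str(ratio_path)
        if cfg.write_rij:
            for lam in rec.lambda_grid:
                mpath = outdir / f"rij_{cond}_lam{lam:g}.tsv"
                write_matrix(mpath, rec.ensembles[lam].F_mean, "r_ij")
                manifest["outputs"][f"rij_lam{lam:g}"] = str(mpath)
    elif cond.startswith("perturbed"):
        parts = cond.split(":")
        kind = parts[1] if len(parts) > 1 else "hubs"
        if kind == "hubs":
            K = p.hubs
        elif kind == "random":
            rng = np.random.default_rng(cfg.base_seed)
            K = np.sort(rng.choice(c.N, size=max(p.hubs.size, 1), replace=False))
        elif kind == "module":
            K = p.members(int(parts[2]))
        else:
            raise ValidationError(cond, [f"unknown perturbation target {kind!r}"])
        track = ex.track_frequencies(c, p, cfg.lambda_grid, cfg.track_trials,
                                     cfg.base_seed, perturbed=K, cfg=osc,
                                     condition=cond)
        tpath = outdir / f"freqtrack_{kind}.tsv"
        groups = sorted(track.freqs[track.lambda_grid[0]].keys(), key=str)
        with open(tpath, "w") as fh:
            fh.write("# dominant angular frequency per group (radians/time)\n")
            fh.write("lambda\t" + "\t".join(map(str, groups)) + "\n")
            for lam in track.lambda_grid:
                means = track.group_means(lam)
                fh.write(f"{lam:g}\t" + "\t".join(f"{means[g]:.6f}" for g in groups) + "\n")
        sync_at = ex.whole_brain_sync_point(track)
        manifest["outputs"]["freqtrack"] = str(tpath)
        manifest["whole_brain_sync_lambda"] = sync_at
        manifest["perturbed_nodes"] = np.asarray(K).tolist()
    else:
        raise ValidationError(cond, [f"unknown condition {cond!r}"])

    manifest["checksums"] = {k: _sha256(Path(v))
                             for k, v in manifest["outputs"].items()}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    log.info("wrote %s", mpath)
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _apply_config_file(ctx, param, value):
    if value:
        with open(value) as fh:
            ctx.default_map = yaml.safe_load(fh) or {}
    return value


_common = [
    click.option("--adjacency", "-a", required=True, help="adjacency TSV / edge list"),
    click.option("--partition", "-p", required=True, help="node->module TSV"),
    click.option("--hubs", "-H", default=None, help="hub list (one node id per line)"),
    click.option("--outdir", "-o", default="hubsync_out"),
    click.option("--lambda-grid", default=None,
                 help="comma-separated couplings, e.g. 0.01,0.02,0.03"),
    click.option("--n-trials", default=100, show_default=True),
    click.option("--t-total", "T", default=700.0, show_default=True),
    click.option("--tau", default=300.0, show_default=True),
    click.option("--dt", default=0.05, show_default=True),
    click.option("--seed", "base_seed", default=0, show_default=True),
    click.option("--config", type=click.Path(exists=True), is_eager=True,
                 expose_value=False, callback=_apply_config_file,
                 help="YAML file of defaults for any flag"),
]


def _with_common(f):
    for opt in reversed(_common):
        f = opt(f)
    return f


def _mk_config(kw, condition) -> RunConfig:
    grid = kw.pop("lambda_grid", None)
    cfg = RunConfig(condition=condition, **kw)
    if grid:
        cfg.lambda_grid = tuple(float(x) for x in str(grid).split(","))
    return cfg


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose):
    """Kuramoto-model analysis of hub-mediated synchrony on connectomes."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--kind", type=click.Choice(["human", "macaque"]), default="human",
              show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--outdir", "-o", default="hubsync_synth")
def synth(kind, seed, outdir):
    """Generate a synthetic rich-club connectome + partition + hub list."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "human":
        spec = sd.SynthSpec(seed=seed)
        c, p = sd.generate_connectome(spec)
    else:
        c, p = sd.generate_macaque_like(seed=seed)
        spec = f"macaque-like defaults, seed={seed}"
    cn.write_adjacency(out / "adjacency.tsv", c)
    cn.write_partition(out / "partition.tsv", p)
    cn.write_hub_list(out / "hubs.txt", p.hubs)
    (out / "provenance.txt").write_text(f"spec: {spec}\n")
    click.echo(f"N={c.N} E={c.n_edges} density={c.density:.3f} "
               f"modules={len(p.module_ids)} hubs={p.hubs.size} -> {out}/")


@cli.command()
@click.argument("path", type=click.Path(exists=True))
def validate(path):
    """Validate an adjacency matrix file; list every violation."""
    try:
        c = validate_adjacency(path)
    except ValidationError as err:
        for d in err.diagnostics:
            click.echo(f"VIOLATION: {d}", err=True)
        raise SystemExit(1)
    click.echo(f"OK: N={c.N} E={c.n_edges} density={c.density:.3f}")


@cli.command(name="simulate")
@click.option("--adjacency", "-a", required=True)
@click.option("--lam", default=0.02, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "-o", default="trajectory.tsv")
def simulate_cmd(adjacency, lam, seed, out):
    """Integrate one Kuramoto trial and write the phase trajectory."""
    c = validate_adjacency(adjacency)
    cfg = OscillatorConfig(lam=lam, seed=seed)
    traj = simulate(cfg, c)
    write_trajectory(out, traj, cfg)
    click.echo(f"wrote {out} ({traj.N} nodes x {traj.n_times} samples)")


def _pipeline_command(name, condition, help_text):
    @cli.command(name=name, help=help_text)
    @_with_common
    def _cmd(**kw):
        cfg = _mk_config(kw, condition)
        try:
            manifest = run_pipeline(cfg)
        except ValidationError as err:
            click.echo(f"error: {err}", err=True)
            raise SystemExit(1)
        click.echo(json.dumps({k: manifest[k] for k in ("outputs",)}, indent=2))
    return _cmd


sweep = _pipeline_command("sweep", "normal",
                          "Coupling sweep on the unmodified network.")
suppress = _pipeline_command("suppress", "hub_suppressed",
                             "Sweep with all hub-hub edges removed.")
suppress_random = _pipeline_command("suppress-random", "random_suppressed",
                                    "Sweep with an equal number of random edges removed.")
perturb = _pipeline_command("perturb", "perturbed:hubs",
                            "Frequency-perturb the hub set (+1) and track module frequencies.")
freqtrack = _pipeline_command("freqtrack", "perturbed:hubs",
                              "Alias of perturb: modular dominant-frequency tracking.")


if __name__ == "__main__":
    cli()
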