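"""End-to-end orchestration: preprocess -> fit -> regress -> report.

Stage interfaces are file-based so each stage can be rerun in isolation:
recordings come in as CSV, per-subject CAS estimates go out as one CSV
row each, posterior draws as a columnar CSV (chain/iteration index
columns plus one column per coefficient), SEXIT summaries as CSV and
diagnostics as JSON.  Every run writes a manifest embedding the config,
its hash, the seed and per-stage counts; two runs with equal config
hashes and seeds are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .fitting import fit_cas
from .inference import (
    PosteriorDraws,
    RegressionSpec,
    diagnostics,
    fit_multivariate_regression,
    sexit_summary,
)
from .io import read_cas_table, read_immune_table, read_rri_file, write_cas_table
from .params import CAS_PARAM_NAMES, ParameterBounds, ProtocolTiming
from .preprocess import EctopicConfig, FilterConfig, preprocess

__all__ = ["PipelineConfig", "run_pipeline", "report", "draws_to_frame"]

logger = logging.getLogger("cardiocas")


@dataclass
class PipelineConfig:
    recordings_dir: Union[str, Path] = "recordings"
    immune_table: Union[str, Path] = "immune.csv"
    output_dir: Union[str, Path] = "output"
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    ectopic_cfg: EctopicConfig = field(default_factory=EctopicConfig)
    protocol: ProtocolTiming = field(default_factory=ProtocolTiming)
    regression: RegressionSpec = field(default_factory=RegressionSpec)
    fit_confounder_model: bool = True
    preprocess_order: str = "ectopic_first"
    n_starts: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def echo(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, (Path,)):
                return str(v)
            if isinstance(v, (tuple, list)):
                return [enc(x) for x in v]
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        blob = json.dumps(self.echo(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        sub = {
            "filter_cfg": FilterConfig,
            "ectopic_cfg": EctopicConfig,
            "protocol": ProtocolTiming,
            "regression": RegressionSpec,
        }
        for k, v in raw.items():
            if k in sub:
                kw[k] = sub[k](**v)
            else:
                kw[k] = v
        return cls(**kw)


def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Columnar layout of the posterior: chain, iteration, then one
    column per ``response:coefficient``."""
    any_resp = next(iter(draws.draws.values()))
    chains, its = next(iter(any_resp.values())).shape
    out = {
        "chain": np.repeat(np.arange(chains), its),
        "iteration": np.tile(np.arange(its), chains),
    }
    for resp in draws.responses:
        for name in draws.coef_names:
            out[f"{resp}:{name}"] = draws.draws[resp][name].reshape(-1)
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full two-stage analysis and write all artifacts.

    Any stage failure aborts with the stage name and subject id; the
    manifest is written with ``"incomplete": true`` before the error
    propagates so partial outputs are identifiable.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "run.log"
    fh = logging.FileHandler(log_file)
    logger.addHandler(fh)

    manifest = {
        "config": config.echo(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "counts": {},
        "warnings": [],
        "incomplete": True,
    }
    _write_json(out / "manifest.json", manifest)

    try:
        rec_files = sorted(Path(config.recordings_dir).glob("*.csv"))
        if not rec_files:
            raise RuntimeError(f"no recordings found in {config.recordings_dir}")
        manifest["counts"]["recordings_in"] = len(rec_files)

        rows, reports = [], []
        bounds = ParameterBounds.for_protocol(config.protocol)
        for path in rec_files:
            sid = path.stem
            stage = "read"
            try:
                rec = read_rri_file(path)
                stage = "preprocess"
                cleaned, rep = preprocess(
                    rec, config.filter_cfg, config.ectopic_cfg, config.preprocess_order
                )
                reports.append(rep)
                stage = "fit_cas"
                fit = fit_cas(
                    cleaned,
                    bounds=bounds,
                    n_starts=config.n_starts,
                    seed=config.seed,
                    protocol=config.protocol,
                )
                rows.append(fit.as_row(sid))
                logger.info("fit %s: loss=%.1f converged=%s", sid, fit.loss, fit.converged)
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed for subject {sid!r}: {exc}"
                ) from exc

        cas_df = write_cas_table(rows, out / "cas.csv")
        _write_json(out / "cleaning_reports.json", reports)
        manifest["counts"]["cas_rows"] = len(cas_df)

        immune = read_immune_table(config.immune_table)
        manifest["counts"]["immune_rows"] = len(immune)

        results = {"cas_table": cas_df, "models": {}}
        model_specs = {"model1": dataclasses.replace(
            config.regression, include_confounders=False, seed=config.seed
        )}
        if config.fit_confounder_model:
            model_specs["model2"] = dataclasses.replace(
                config.regression, include_confounders=True, seed=config.seed
            )
        for tag, spec in model_specs.items():
            try:
                draws = fit_multivariate_regression(cas_df, immune, spec)
                sexit = sexit_summary(draws)
                diag = diagnostics(draws, seed=config.seed)
            except Exception as exc:
                raise RuntimeError(f"stage 'regression ({tag})' failed: {exc}") from exc
            draws_to_frame(draws).to_csv(out / f"draws_{tag}.csv", index=False)
            sexit.to_csv(out / f"sexit_{tag}.csv", index=False)
            _write_json(out / f"diagnostics_{tag}.json", diag)
            manifest["counts"][f"sexit_rows_{tag}"] = len(sexit)
            results["models"][tag] = {"draws": draws, "sexit": sexit, "diagnostics": diag}

        manifest["incomplete"] = False
        return {**results, "manifest": manifest, "output_dir": out}
    finally:
        _write_json(out / "manifest.json", manifest)
        logger.removeHandler(fh)
        fh.close()


def report(output_dir: Union[str, Path], make_plots: bool = True) -> str:
    """Human-readable run summary, regenerated purely from saved artifacts.

    Renders the cohort CAS table (mean and 95% interval per parameter)
    and the per-predictor SEXIT tables; optionally writes trajectory and
    posterior-density figures next to the artifacts.
    """
    from scipy import stats

    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    if manifest.get("incomplete"):
        raise RuntimeError("run marked incomplete; not generating a report")
    cas = read_cas_table(out / "cas.csv")

    lines = []
    lines.append("Cohort cardiac autonomic signature")
    lines.append(f"  n = {len(cas)} subjects, seed = {manifest['seed']}, "
                 f"config = {manifest['config_hash']}")
    lines.append(f"  {'param':>6} {'mean':>10} {'95% CI':>22}")
    n = len(cas)
    tcrit = stats.t.ppf(0.975, n - 1)
    for k in CAS_PARAM_NAMES:
        v = cas[k].to_numpy(float)
        m = v.mean()
        half = tcrit * v.std(ddof=1) / np.sqrt(n)
        lines.append(f"  {k:>6} {m:>10.2f} [{m - half:>9.2f}, {m + half:>9.2f}]")

    for tag in ("model1", "model2"):
        f = out / f"sexit_{tag}.csv"
        if not f.exists():
            continue
        sexit = pd.read_csv(f)
        label = "immune predictors only" if tag == "model1" else "confounder-adjusted"
        lines.append("")
        lines.append(f"Standardized effects ({label})")
        lines.append(f"  {'response':>8} {'coefficient':>14} {'ES':>7} "
                     f"{'95% HDI':>18} {'pd':>6} {'ps':>6}")
        for _, r in sexit.iterrows():
            if r["coefficient"] == "Intercept":
                continue
            lines.append(
                f"  {r['response']:>8} {r['coefficient']:>14} {r['median']:>7.2f} "
                f"[{r['hdi_low']:>7.2f}, {r['hdi_high']:>7.2f}] "
                f"{r['pd']:>6.3f} {r['ps']:>6.3f}"
            )

    text = "\n".join(lines)
    (out / "report.txt").write_text(text + "\n")
    if make_plots:
        _plots(out, manifest, cas)
    return text


def _plots(out: Path, manifest: dict, cas: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import evaluate_model

    rec_dir = Path(manifest["config"]["recordings_dir"])
    files = sorted(rec_dir.glob("*.csv"))[:6]
    if files:
        fig, axes = plt.subplots(
            len(files), 1, figsize=(8, 2.2 * len(files)), squeeze=False, sharex=True
        )
        for ax, path in zip(axes[:, 0], files):
            rec = read_rri_file(path)
            row = cas[cas["subject_id"] == path.stem]
            ax.plot(rec.beat_times, rec.intervals, ".", ms=2, alpha=0.5, label="RRi")
            if len(row):
                theta = row.iloc[0][list(CAS_PARAM_NAMES)].to_numpy(float)
                tt = np.linspace(rec.beat_times[0], rec.beat_times[-1], 500)
                ax.plot(tt, evaluate_model(tt, theta), "r-", lw=1.5, label="fit")
            ax.set_ylabel(f"{path.stem}\nRRi (ms)")
            ax.legend(loc="lower left", fontsize=7)
        axes[-1, 0].set_xlabel("time (min)")
        fig.tight_layout()
        fig.savefig(out / "trajectories.png", dpi=120)
        plt.close(fig)

    for tag in ("model1", "model2"):
        f = out / f"draws_{tag}.csv"
        if not f.exists():
            continue
        draws = pd.read_csv(f)
        cols = [
            c
            for c in draws.columns
            if ":" in c and not c.endswith(":sigma") and not c.endswith(":Intercept")
        ]
        ncol = 6
        nrow = int(np.ceil(len(cols) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(2.4 * ncol, 1.8 * nrow))
        for ax, c in zip(np.ravel(axes), cols):
            x = draws[c].to_numpy()
            ax.hist(x, bins=50, density=True, color="#4477aa")
            ax.axvspan(-0.1, 0.1, color="grey", alpha=0.35)  # ROPE
            ax.set_title(c, fontsize=7)
            ax.set_yticks([])
        for ax in np.ravel(axes)[len(cols):]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / f"posteriors_{tag}.png", dpi=120)
        plt.close(fig)


def _versions() -> dict:
    import arviz
    import scipy

    return {
        "cardiocas": _pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
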