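"""End-to-end orchestration: generate -> index -> rates -> fit -> simulate.

One :class:`RunConfig` (optionally loaded from YAML) drives a full
reproducible run: the synthetic tables are generated from the seed, the LTU
propensity quintiles constructed, visit rates computed for the most frequent
conditions, each condition regressed with robust variance, and the Q1
counterfactual simulated.  Every artifact is plain text under one run
directory, records the seed in its header, and is listed with a SHA-256
digest in ``manifest.json`` — identical config and seed give identical
digests.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, ltu, regress, simulate, synth, visits
from .exceptions import ConfigurationError

log = logging.getLogger("ltued")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All settings of one pipeline run.

    ``generator`` holds keyword overrides passed through to
    :class:`ltued.synth.GeneratorConfig` (for example ``population_range`` or
    ``noise_fraction``); everything else configures the analysis stages.
    """

    out_dir: str | Path = "run"
    seed: int = 0
    n_zcta: int = 392
    top_k: int = 15
    replace_mode: str = "q2q5"  # or "q2q4"
    cov_type: str = "HC1"  # or HC0 / HC3
    propensity_spec: str = "fractional"  # or "median-binary"
    covariate_scale: str = "percent"  # or "fraction"
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.top_k < 1:
            raise ConfigurationError(f"top_k must be >= 1, got {self.top_k}")
        if self.replace_mode not in simulate.REPLACE_MODES:
            raise ConfigurationError(f"unknown replace_mode {self.replace_mode!r}")
        if self.propensity_spec not in ("fractional", "median-binary"):
            raise ConfigurationError(f"unknown propensity_spec {self.propensity_spec!r}")
        if self.covariate_scale not in ("percent", "fraction"):
            raise ConfigurationError(f"unknown covariate_scale {self.covariate_scale!r}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context manager logging a stage's wall time to stderr."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.2fs (%s)", self.name, dt, exc)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the artifact manifest.

    Any stage failure propagates as an :class:`LtuedError` (or subclass)
    after being logged with the stage name; the CLI maps that to a nonzero
    exit status.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    written: list[Path] = []

    def emit(df, rel, **kw):
        path = io.write_table(df, out / rel, seed=seed, **kw)
        written.append(path)
        return path

    with _Stage("generate"):
        gen_cfg = synth.GeneratorConfig(
            n_zcta=config.n_zcta, seed=seed, **config.generator
        )
        zcta_table, truth = synth.generate_zcta_table(gen_cfg)
        records = synth.generate_visits(zcta_table, truth, gen_cfg)
        emit(zcta_table, "zcta.csv")
        emit(records, "visits.csv")
        gt_path = io.write_json(
            {
                "latent_quintile": truth.latent_quintile.to_dict(),
                "n_qualifying": truth.n_qualifying,
                "n_noise": truth.n_noise,
            },
            out / "ground_truth.json",
            seed=seed,
        )
        written.append(gt_path)

    with _Stage("ltu-index"):
        model = ltu.fit_propensity(zcta_table, spec=config.propensity_spec)
        scores = ltu.score_propensity(model, zcta_table)
        assignments = ltu.assign_quintiles(scores)
        emit(assignments, "assignments.csv")

    with _Stage("rates"):
        kept, tally = visits.filter_encounters(records, zcta_table["zcta_id"])
        top = visits.tabulate_conditions(kept, config.top_k)
        conditions = [c for c, _ in top]
        panel = visits.compute_rates(kept, zcta_table, conditions)
        emit(panel.to_long(), "rates.csv")
        tally_path = io.write_json(tally.__dict__, out / "filter_tally.json", seed=seed)
        written.append(tally_path)

    with _Stage("fit"):
        fits = {}
        designs = {}
        for cond in conditions:
            spec = regress.DesignSpec.for_condition(
                cond, covariate_scale=config.covariate_scale
            )
            y, X, terms = regress.build_design(panel, zcta_table, assignments, spec)
            fit = regress.fit_ols_robust(
                y, X, terms, cov_type=config.cov_type, condition=cond
            )
            fits[cond] = fit
            designs[cond] = X
            emit(fit.report_frame(), Path("fits") / f"{cond}.csv")
            fp = io.write_json(fit.to_dict(), out / "fits" / f"{cond}.json", seed=seed)
            written.append(fp)
        summary, counts = regress.summarize_quintile_effects(list(fits.values()))
        emit(summary, "quintile_summary.csv")
        written.append(io.write_json(counts, out / "effect_counts.json", seed=seed))

    with _Stage("simulate"):
        report = simulate.summarize_simulation(
            panel, zcta_table, fits, designs, mode=config.replace_mode
        )
        emit(report, "simulation.csv")
        desc = simulate.quintile_descriptives(zcta_table, assignments, panel)
        emit(desc, "descriptives.csv")

    manifest = {
        "seed": seed,
        "n_zcta": config.n_zcta,
        "files": {str(p.relative_to(out)): _digest(p) for p in written},
    }
    io.write_json(manifest, out / "manifest.json")
    log.info("wrote %d artifacts to %s", len(written), out)
    return manifest
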