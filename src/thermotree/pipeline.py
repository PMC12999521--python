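"""End-to-end orchestration: simulate -> assay stats -> phylo -> TDT -> protein.

A :class:`RunConfig` fully determines a run; all randomness derives from
its seed and every output CSV carries a header with the package version,
seed, and a hash of the configuration.  Stages never mutate their inputs;
each writes fresh files into the output directory and a log records stage
timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import assay_stats, io as tio, phylo, protein_tm, synthdata, tdt
from .errors import SchemaError

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("thermotree")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "thermotree_out"
    simulate: bool = True
    n_tips: int = 200
    # paths used when simulate=False
    assays: str | None = None
    plots: str | None = None
    series: str | None = None
    tree: str | None = None
    tm_table: str | None = None
    scenarios: tuple = ("current", "ssp126", "ssp370", "ssp585")
    z: float = 3.0
    t_ref: float = 1.0
    threshold_min: float = 480.0
    quantiles: tuple = (0.10, 0.25, 0.50)
    bands: tuple = (600.0, 1200.0)
    n_permutations: int = 199

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location is not part of the analysis
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate(self) -> None:
        if not self.simulate:
            required = {"assays": self.assays, "plots": self.plots,
                        "series": self.series, "tree": self.tree}
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise SchemaError(
                    f"simulate=False requires input paths: {', '.join(missing)}"
                )
            for name, p in required.items():
                if not Path(p).exists():
                    raise SchemaError(f"{name} path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the in-memory results bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {"config_hash": chash}

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            out = fn()
        except Exception:
            log.exception("stage %s: FAILED", name)
            raise
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
        return out

    try:
        if config.simulate:
            sim_cfg = synthdata.SimConfig(seed=config.seed, n_tips=config.n_tips)
            bundle = stage(
                "simulate", lambda: synthdata.generate_all(sim_cfg, outdir / "inputs")
            )
            assays, plots = bundle["assays"], bundle["plots"]
            series, tree = bundle["series"], bundle["tree"]
            trait, tm_table = bundle["trait"], bundle["tm_table"]
        else:
            assays = tio.read_assays(config.assays)
            plots = tio.read_plots(config.plots)
            series = tio.read_series(config.series)
            tree = __import__("thermotree.trees", fromlist=["CalibratedTree"]) \
                .CalibratedTree.read_newick(config.tree)
            trait = None
            tm_table = tio.read_tm(config.tm_table) if config.tm_table else None

        # --- assay statistics ---------------------------------------
        def assay_stage():
            summaries = assay_stats.summarize_plots(assays, plots)
            trend = None
            hot = summaries[summaries["direction"] == "ctmax"]
            if len(hot) >= 3:
                trend = assay_stats.fit_elevation_trend(
                    hot["elevation"].to_numpy(), hot["mean"].to_numpy(), "linear"
                )
            margins = assay_stats.thermal_range_and_margin(summaries)
            shocks = assay_stats.shock_effect(assays, config.bands)
            tio.write_table(summaries, outdir / "plot_summaries.csv",
                            config.seed, chash)
            tio.write_table(margins, outdir / "margins.csv", config.seed, chash)
            if not shocks.empty:
                tio.write_table(shocks, outdir / "shock_effects.csv",
                                config.seed, chash)
            return {"summaries": summaries, "trend": trend,
                    "margins": margins, "shocks": shocks}

        results["assay"] = stage("assay-stats", assay_stage)

        # --- phylogenetic comparative -------------------------------
        def phylo_stage():
            if trait is None:
                y = assays[assays["direction"] == "ctmax"].groupby("otu_id")[
                    "ct_value"
                ].mean()
            else:
                y = trait
            elev = assays.groupby("otu_id")["elevation"].mean() \
                if "otu_id" in assays.columns else None
            lam = phylo.pagel_lambda(tree, y)
            k = phylo.blomberg_k(tree, y, n_perm=config.n_permutations,
                                 seed=config.seed)
            ou = phylo.fit_ou_optimum(tree, y)
            fits = {}
            if elev is not None:
                pred = pd.DataFrame({"elevation": elev.reindex(y.index)})
                for model in ("BM", "OU", "star"):
                    fits[model] = phylo.pgls_fit(tree, y, pred, model)
                ranking = phylo.compare_models(fits.values())
                partition = phylo.variance_partition(tree, y, pred, "OU")
            else:
                ranking, partition = None, {}
            anc = phylo.ancestral_states(tree, y)
            tio.write_table(anc.reset_index(), outdir / "ancestral_states.csv",
                            config.seed, chash)
            summary = pd.DataFrame(
                [{"lambda": lam.lambda_hat, "lambda_p": lam.p_value,
                  "K": k.k_hat, "K_p": k.p_value, "theta": ou.theta,
                  "alpha": ou.alpha, "sigma2": ou.sigma2}]
            )
            tio.write_table(summary, outdir / "phylo_summary.csv",
                            config.seed, chash)
            return {"lambda": lam, "K": k, "ou": ou, "fits": fits,
                    "ranking": ranking, "partition": partition,
                    "ancestral": anc}

        results["phylo"] = stage("phylo", phylo_stage)

        # --- thermal death time -------------------------------------
        def tdt_stage():
            policy = tio.QCPolicy()
            clean = [tio.apply_qc(s, policy) for s in series]
            clean = [s for s in clean if len(s)]
            hot = assays[assays["direction"] == "ctmax"]
            lowest = hot.loc[hot["elevation"] == hot["elevation"].min()]
            sens = tdt.community_sensitivity(
                lowest["ct_value"].to_numpy(), config.quantiles,
                z=config.z, t_ref=config.t_ref,
            )
            scenarios = [s for s in config.scenarios
                         if s == "current" or f"bio5_{s}" in plots.columns]
            summary = tdt.summarize_coma(clean, sens, plots, scenarios,
                                         config.threshold_min)
            tio.write_table(summary, outdir / "coma_summary.csv",
                            config.seed, chash)
            return {"sensitivities": sens, "summary": summary}

        results["tdt"] = stage("tdt", tdt_stage)

        # --- protein melting temperatures ---------------------------
        if tm_table is not None:
            def protein_stage():
                sens_tm = protein_tm.sensitive_quantile_mean(tm_table)
                meta = tm_table.drop_duplicates("species_id").set_index(
                    "species_id"
                )
                fam_tm = sens_tm.groupby(meta["family"]).mean()
                counts = meta.groupby("family").size().astype(float)
                hot = assays[assays["direction"] == "ctmax"]
                fam_ct = hot.groupby("family")["ct_value"].mean() \
                    if "family" in hot.columns else pd.Series(dtype=float)
                fits = None
                common = fam_tm.index.intersection(fam_ct.index)
                if len(common) >= 3:
                    fits = protein_tm.family_tm_vs_ctmax(
                        fam_tm, fam_ct, counts
                    )
                tests = protein_tm.tm_variance_tests(tm_table)
                tio.write_table(
                    sens_tm.rename("tm_sensitive").reset_index(),
                    outdir / "species_tm.csv", config.seed, chash,
                )
                return {"species_tm": sens_tm, "family_tm": fam_tm,
                        "fits": fits, "variance_tests": tests}

            results["protein"] = stage("protein", protein_stage)
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
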