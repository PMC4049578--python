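"""End-to-end orchestration: sequences + metadata -> tables, fits, tree.

A run is fully described by a :class:`RunConfig`; the config, input
checksums and package version are serialized into the output directory as a
manifest, so every output file is re-derivable from the manifest alone.
The pipeline is deterministic: no timestamps or unseeded randomness enter
the result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, allometry, composition, hydropathy, phylo_nj, regression_stats
from . import sequence_io

log = logging.getLogger("mmpkit")


@dataclass
class RunConfig:
    fasta: str
    metadata: str
    outdir: str
    scale_file: str | None = None        # None -> Cowan-Whittaker default
    iterations: int = hydropathy.DEFAULT_ITERATIONS
    convergence_tol: float | None = None
    domain: str = composition.FULL_SEQUENCE
    protein_sets: list[str] = field(
        default_factory=lambda: list(composition.NESTED_SETS) + ["all13"]
    )
    f_grid: list[float] = field(default_factory=lambda: list(allometry.DEFAULT_F_GRID))
    sweep_set: str = "set3"              # set used for the STC-ln(mtBMR) sweep
    table1_mode: str = "group_mean"
    regression_set: str = "set5"         # set of the headline TC-HYD fits
    nj_set: str = "set5"
    nj_variables: list[str] = field(default_factory=lambda: ["TC", "TSN"])
    outgroup: str | None = None
    seed: int = 0                        # reserved for resampling extensions
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``config.outdir``.

    Returns a dict with the in-memory results and the output paths.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    # run.log: stage log with wall-clock timings (informational only; the
    # one output file that is not byte-reproducible between runs)
    run_log = logging.FileHandler(out / "run.log", mode="w")
    run_log.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(run_log)
    t_start = time.perf_counter()

    def stage_done(name: str) -> None:
        log.info("stage %-12s done at %.2fs", name, time.perf_counter() - t_start)

    scale = (
        hydropathy.load_scale(config.scale_file)
        if config.scale_file
        else hydropathy.cowan_whittaker()
    )
    read = sequence_io.read_fasta(config.fasta)
    metadata = sequence_io.read_metadata(config.metadata)
    log.info("read %d records (%d rejected), %d metadata groups",
             len(read.records), len(read.rejects), len(metadata))
    report = sequence_io.validate_dataset(read.records, metadata)
    sequence_io.write_validation_report(report, out / "validation.json")
    if read.rejects:
        _write_tsv(read.reject_frame(), out / "rejects.tsv")
    stage_done("validate")

    # composition tables, per protein set
    species_frames: dict[str, pd.DataFrame] = {}
    group_frames: dict[str, pd.DataFrame] = {}
    for set_name in config.protein_sets:
        pset = composition.PROTEIN_SETS[set_name]
        sp = composition.species_table(
            read.records, pset, scale, config.iterations, config.domain
        )
        species_frames[set_name] = sp
        if not sp.empty:
            group_frames[set_name] = composition.group_mean(sp)
    tidy = pd.concat(
        [
            df.assign(protein_set=name, domain=config.domain, unit=level)
            for frames, level in ((species_frames, "species"), (group_frames, "group"))
            for name, df in frames.items()
        ],
        ignore_index=True,
    )
    _write_tsv(tidy, out / "composition.tsv")
    stage_done("composition")

    # per-gene correlation table
    table1 = regression_stats.build_table1(
        read.records, scale, config.iterations, config.domain, config.table1_mode
    )
    _write_tsv(table1, out / "table1.tsv")
    stage_done("table1")

    # F-sweep on the sweep set's group-mean STC
    sweep = None
    sweep_groups = group_frames.get(config.sweep_set)
    if sweep_groups is not None and len(sweep_groups) >= 3:
        stc = dict(zip(sweep_groups["group"], sweep_groups["STC"]))
        try:
            sweep = allometry.f_sweep(metadata, stc, config.f_grid)
            _write_tsv(sweep.frame(), out / "fsweep.tsv")
            _write_tsv(
                pd.DataFrame(
                    sorted(sweep.mtbmr_at_best.items()), columns=["group", "mtBMR"]
                ),
                out / "mtbmr_at_best_F.tsv",
            )
        except ValueError as exc:
            log.warning("F-sweep skipped: %s", exc)

    # cross-set correlation table at the sweep's best F (fall back to inf)
    best_f = sweep.best_F if sweep is not None else float("inf")
    nested = {
        name: df for name, df in group_frames.items()
        if name in composition.NESTED_SETS
    }
    results: dict = {
        "read": read, "metadata": metadata, "validation": report,
        "species": species_frames, "groups": group_frames,
        "table1": table1, "sweep": sweep,
    }
    if nested and len(metadata) >= 3:
        table2 = regression_stats.build_table2(nested, metadata, F=best_f)
        _write_tsv(table2, out / "table2.tsv")
        _write_tsv(
            regression_stats.table2_wide(table2), out / "table2_wide.tsv", index=True
        )
        results["table2"] = table2

    # headline regressions on the regression set
    reg_rows = []
    reg_groups = group_frames.get(config.regression_set)
    if reg_groups is not None and len(reg_groups) >= 3:
        try:
            power = regression_stats.fit_power(reg_groups["HYD"], reg_groups["TC"])
            reg_rows.append(
                {"fit": "TC~HYD_power", "subset": "all", **power.params,
                 "r2": power.r2, "n": power.n}
            )
        except ValueError as exc:
            log.warning("power fit skipped: %s", exc)
        for xvar, yvar in (("HYD", "TC"), ("TSN", "TC"), ("TSN", "HYD")):
            fits = regression_stats.split_linear_fits(reg_groups, metadata, xvar, yvar)
            for name, fit in fits.items():
                reg_rows.append(
                    {"fit": f"{yvar}~{xvar}_linear", "subset": name, **fit.params,
                     "r2": fit.r2, "n": fit.n}
                )
        # two-predictor fit: ln(mtBMR) on STC and HYD
        aug = regression_stats._augment_with_metadata(reg_groups, metadata, F=best_f)
        if len(aug) >= 4:
            ml = regression_stats.multi_linear(aug["ln_mtBMR"], aug["STC"], aug["HYD"])
            reg_rows.append(
                {"fit": "ln_mtBMR~STC+HYD", "subset": "all", **ml.params,
                 "r2": ml.r2, "n": ml.n}
            )
    if reg_rows:
        reg_df = pd.DataFrame(reg_rows)
        _write_tsv(reg_df, out / "regressions.tsv")
        results["regressions"] = reg_df

    # neighbor-joining tree in (TC, TSN) space
    nj_groups = group_frames.get(config.nj_set)
    if nj_groups is not None and len(nj_groups) >= 3:
        spec = phylo_nj.TraitDistanceSpec(
            variables=tuple(config.nj_variables), protein_set=config.nj_set
        )
        tree = phylo_nj.build_trait_tree(nj_groups, spec, outgroup=config.outgroup)
        phylo_nj.write_newick(tree, out / "tree.nwk")
        phylo_nj.write_distance_tsv(tree, out / "trait_distances.tsv")
        results["tree"] = tree
    stage_done("tree")

    # outdir is location metadata, not part of the reproducible recipe
    config_dict = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
    }
    manifest = {
        "package": "mmpkit",
        "version": __version__,
        "config": config_dict,
        "inputs": {
            "fasta_sha256": _sha256(config.fasta),
            "metadata_sha256": _sha256(config.metadata),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    stage_done("manifest")
    log.removeHandler(run_log)
    run_log.close()
    results["outdir"] = out
    return results
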