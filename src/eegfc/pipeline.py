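"""End-to-end orchestration: simulate -> preprocess -> features -> stats -> classify."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BAND_NAMES
from .classify import (DEFAULT_GRID, conditional_shap, feature_importance,
                       fit_l2_logistic, loo_predict, nested_cv, table_to_xy,
                       _grid_search)
from .connectivity import (band_phase_epochs, connectivity_feature_table,
                           subject_connectivity)
from .preprocessing import extract_epochs, preprocess
from .recording import GROUP_A, GROUP_B, Recording
from .simulate import (SimulationConfig, config_from_dict, default_config,
                       generate_cohort, load_cohort, write_cohort)
from .spectral import spectral_feature_table, subject_spectral_features
from .stats import (friedman_channel_effect, friedman_group_effect,
                    mass_univariate)

log = logging.getLogger("eegfc")

FEATURE_SETS = ("spectral", "plv", "ciplv")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulation: Optional[SimulationConfig] = None
    edf_dir: Optional[Path] = None
    feature_sets: Sequence[str] = FEATURE_SETS
    q: float = 0.05
    outer_splits: int = 6
    inner_splits: int = 5
    grid: Sequence[float] = DEFAULT_GRID
    shap_permutations: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.edf_dir is None:
            raise ValueError("either a simulation config or an EDF directory "
                             "must be supplied")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets {sorted(unknown)}; "
                             f"choose from {FEATURE_SETS}")
        if not self.feature_sets:
            raise ValueError("at least one feature set must be selected")
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        sim = doc.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            preset = sim.pop("preset", None)
            if preset == "default":
                sim = default_config(**sim)
            elif preset == "null":
                sim = default_config(group_effect=False, **sim)
            else:
                sim = config_from_dict(sim)
        edf_dir = doc.pop("edf_dir", None)
        return cls(simulation=sim,
                   edf_dir=Path(edf_dir) if edf_dir else None, **doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, subject: str = "") -> None:
    log.info("stage=%s%s", name, f" subject={subject}" if subject else "")


def compute_feature_tables(recordings: Sequence[Recording],
                           feature_sets: Sequence[str]) -> Dict[str, pd.DataFrame]:
    """Preprocess every recording and build the requested feature tables."""
    want_conn = {"plv", "ciplv"} & set(feature_sets)
    spectral_rows, conn_rows = [], {m: [] for m in want_conn}
    for rec in recordings:
        _stage("preprocess", rec.subject_id)
        clean = preprocess(rec)
        if "spectral" in feature_sets:
            _stage("spectral", rec.subject_id)
            spectral_rows.append(subject_spectral_features(extract_epochs(clean)))
        if want_conn:
            _stage("connectivity", rec.subject_id)
            phases = band_phase_epochs(clean)
            for measure in want_conn:
                conn_rows[measure].append(subject_connectivity(phases, measure))
    tables: Dict[str, pd.DataFrame] = {}
    if "spectral" in feature_sets:
        tables["spectral"] = spectral_feature_table(spectral_rows)
    for measure in want_conn:
        tables[measure] = connectivity_feature_table(conn_rows[measure])
    return tables


def _stats_outputs(name: str, table: pd.DataFrame, q: float,
                   outdir: Path) -> List[Path]:
    labels = table["group"].to_numpy()
    features = table.drop(columns="group")
    result = mass_univariate(features, labels, group_a=GROUP_A, q=q)
    out = outdir / f"stats_{name}.tsv"
    result.to_frame().to_csv(out, sep="\t")
    written = [out]

    if name == "spectral":
        rows = []
        for band in BAND_NAMES:
            cols = [c for c in features.columns if c.endswith(f"_{band}")]
            vals = features[cols].to_numpy()
            ch = friedman_channel_effect(vals)
            grp = friedman_group_effect(vals[labels == GROUP_A],
                                        vals[labels == GROUP_B])
            rows.append({"band": band,
                         "channels_chi2": ch.statistic, "channels_df": ch.df,
                         "channels_p": ch.p_value,
                         "groups_chi2": grp.statistic, "groups_df": grp.df,
                         "groups_p": grp.p_value})
        fpath = outdir / "friedman_spectral.tsv"
        pd.DataFrame(rows).to_csv(fpath, sep="\t", index=False)
        written.append(fpath)
    else:
        # signed significance maps, one square matrix per band
        sig = result.significant.astype(int) * result.direction
        names = result.feature_names
        channels = sorted({part for n in names
                           for part in n.split("_")[0].split("-")})
        index = {c: i for i, c in enumerate(channels)}
        for band in BAND_NAMES:
            mat = np.zeros((len(channels), len(channels)), dtype=int)
            for n, s in zip(names, sig):
                pair, b = n.split("_")[0], n.split("_")[1]
                if b != band:
                    continue
                a_lbl, b_lbl = pair.split("-")
                mat[index[a_lbl], index[b_lbl]] = s
                mat[index[b_lbl], index[a_lbl]] = s
            mpath = outdir / f"sigmap_{name}_{band}.tsv"
            pd.DataFrame(mat, index=channels, columns=channels).to_csv(
                mpath, sep="\t")
            written.append(mpath)
    return written


def _classify_outputs(name: str, table: pd.DataFrame, config: RunConfig,
                      outdir: Path) -> List[Path]:
    X, y, feature_names, subject_ids = table_to_xy(table, positive_group=GROUP_A)
    written = []

    _stage(f"classify/{name}/nested-cv")
    report = nested_cv(X, y, outer=config.outer_splits, inner=config.inner_splits,
                       grid=config.grid, seed=config.seed)
    cv_path = outdir / f"cv_{name}.json"
    cv_path.write_text(json.dumps(report.to_dict(), indent=2))
    written.append(cv_path)

    _stage(f"classify/{name}/loo")
    loo = loo_predict(X, y, subject_ids, grid=config.grid,
                      inner=config.inner_splits, seed=config.seed)
    loo_path = outdir / f"loo_{name}.json"
    loo_path.write_text(json.dumps(loo.to_dict(), indent=2))
    written.append(loo_path)

    # strip data for probability plots (Fig-4 style)
    strip = pd.DataFrame({"subject_id": loo.subject_ids,
                          "group": table["group"].to_numpy(),
                          "proba_asd_like": loo.proba})
    strip_path = outdir / f"loo_{name}_strip.csv"
    strip.to_csv(strip_path, index=False)
    written.append(strip_path)

    _stage(f"classify/{name}/shap")
    strength = _grid_search(X, y, config.grid, config.inner_splits,
                            seed=config.seed)
    model = fit_l2_logistic(X, y, strength)
    sv, base = conditional_shap(model, X, X,
                                n_permutations=config.shap_permutations,
                                seed=config.seed)
    explanation = feature_importance(sv, table["group"].to_numpy(),
                                     feature_names, base)
    fi_path = outdir / f"fi_{name}.tsv"
    explanation.to_frame().to_csv(fi_path, sep="\t")
    written.append(fi_path)
    return written


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every configured stage; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        _stage("simulate")
        recordings = generate_cohort(config.simulation)
        edf_dir = outdir / "edf"
        write_cohort(recordings, edf_dir)
        recordings = load_cohort(edf_dir)  # analyze the round-tripped data
    else:
        _stage("load")
        recordings = load_cohort(config.edf_dir)

    tables = compute_feature_tables(recordings, config.feature_sets)
    written: List[Path] = []
    feature_counts = {}
    for name, table in tables.items():
        fpath = outdir / f"features_{name}.csv"
        table.to_csv(fpath)
        written.append(fpath)
        feature_counts[name] = table.shape[1] - 1  # minus group column

    for name, table in tables.items():
        _stage(f"stats/{name}")
        written += _stats_outputs(name, table, config.q, outdir)
    for name, table in tables.items():
        written += _classify_outputs(name, table, config, outdir)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": len(recordings),
        "groups": {GROUP_A: sum(r.group_label == GROUP_A for r in recordings),
                   GROUP_B: sum(r.group_label == GROUP_B for r in recordings)},
        "feature_sets": list(config.feature_sets),
        "feature_counts": feature_counts,
        "q": config.q,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
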