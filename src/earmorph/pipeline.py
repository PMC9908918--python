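"""End-to-end orchestration: landmarks + tree + audiograms + traits in,
tables of shape, hearing and comparative statistics out.

Stage order: load or generate -> mirror left sides -> build 130-point
configurations -> per-specimen metrics -> joint GPA -> species consensus
-> PCA and phylogenetic PCA -> phylogenetic signal (K for PC1-3, Kmult)
-> hearing-variable extraction (ABR records corrected first) -> log10
transform of all morphological measures except the cross-section ratio
-> PGLS grids overall and within groups -> Mann-Whitney group
comparisons -> ancestral states of PC1.

Every stage draws randomness only from the run seed, so a (config, seed)
pair reproduces the bundle bit-identically.
"""

from __future__ import annotations

import hashlib
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audiometry, geometry, shape
from .io_formats import (
    AudiogramRecord,
    Phylogeny,
    parse_landmark_file,
    read_audiogram_table,
    read_newick,
    read_trait_table,
    write_results,
)
from .phylo import bm_covariance, blomberg_k, kmult, mann_whitney_u, pgls_fit
from .phylo import ancestral_states
from .synthetic import SyntheticWorld, WorldConfig, generate_world

#: morphological measures; all but CSR are log10-transformed for regression
MORPH_VARS = ("CL", "CW", "NT", "OWA", "ACS", "CSR", "CS")
HEARING_VARS = ("LFC", "ASL", "ASM", "HFC", "ASH", "SPL1", "RO", "MS",
                "PS", "CF1", "CF2")
#: hearing variables on a frequency scale, regressed in log2 (octave) units
FREQ_HEARING_VARS = ("LFC", "HFC", "CF1", "CF2")


@dataclass
class PipelineConfig:
    """Exactly one of (input paths, synthetic world config) drives a run."""

    landmarks_dir: str | None = None
    tree_path: str | None = None
    audiogram_path: str | None = None
    trait_path: str | None = None
    station_areas_path: str | None = None
    synthetic: WorldConfig | None = None
    gpa_order: str = "joint"          # "joint" or "consensus_first"
    nt_rounding: str = "floor"
    cutoff_criterion: float = 60.0
    extrapolation_floor: float = 45.0
    n_perm: int = 999
    seed: int = 0
    outdir: str | None = None
    exclusions: dict = field(default_factory=dict)  # hearing var -> [species]

    def __post_init__(self):
        real = self.landmarks_dir is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of real input paths or a synthetic config is required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            raw["synthetic"] = WorldConfig(**syn) if isinstance(syn, dict) else syn
        raw.pop("config_path", None)
        return cls(**raw)

    def hash(self) -> str:
        d = dict(self.__dict__)
        if isinstance(d.get("synthetic"), WorldConfig):
            d["synthetic"] = d["synthetic"].snapshot()
        blob = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    tables: dict[str, pd.DataFrame]
    log: list[str]
    config_hash: str
    seed: int

    def equals(self, other: "ResultsBundle") -> bool:
        if sorted(self.tables) != sorted(other.tables):
            return False
        return all(self.tables[k].equals(other.tables[k]) for k in self.tables)

    def write(self, outdir: str | Path) -> None:
        header = [f"config_hash: {self.config_hash}", f"seed: {self.seed}"]
        write_results(self.tables, outdir, header_lines=header)
        Path(outdir, "run.log").write_text("\n".join(self.log) + "\n")


# ----------------------------------------------------------- data loading


@dataclass
class _SpecimenData:
    specimen_id: str
    species: str
    side: str
    curve_points: np.ndarray       # LM1, LM2, raw curve..., apex (as read)
    ow_points: np.ndarray
    station_areas: np.ndarray | None


def _load_real(cfg: PipelineConfig):
    lm_dir = Path(cfg.landmarks_dir)
    curves = {}
    ovals = {}
    for path in sorted(lm_dir.glob("*.lmk")):
        lm = parse_landmark_file(path.read_text())
        (curves if lm.structure == "cochlea_curve" else ovals)[lm.specimen_id] = lm
    areas = {}
    if cfg.station_areas_path:
        df = pd.read_csv(cfg.station_areas_path)
        for sid, grp in df.groupby("specimen_id"):
            areas[sid] = grp.sort_values("station")["area_mm2"].to_numpy()
    specimens = []
    for sid in sorted(curves):
        lm = curves[sid]
        if sid not in ovals:
            raise ValueError(f"specimen {sid!r} lacks an oval-window file")
        specimens.append(_SpecimenData(
            sid, lm.species, lm.side, lm.points, ovals[sid].points,
            areas.get(sid)))
    phy = read_newick(cfg.tree_path)
    audiograms = read_audiogram_table(cfg.audiogram_path)
    traits = read_trait_table(cfg.trait_path)
    return specimens, phy, audiograms, traits


def _from_world(world: SyntheticWorld):
    specimens = [
        _SpecimenData(s.specimen_id, s.species, s.side, s.cochlea.points,
                      s.oval_window.points, s.station_areas)
        for s in world.specimens
    ]
    return specimens, world.phylogeny, world.audiograms, world.traits


# ------------------------------------------------------------- the stages


def _specimen_metrics(specimens, nt_rounding):
    rows = []
    configs = []
    for spm in specimens:
        pts = spm.curve_points
        ow = spm.ow_points
        if spm.side == "left":
            pts = geometry.mirror_configuration(pts)
            ow = geometry.mirror_configuration(ow)
        config = geometry.build_configuration(pts[1:], pts[:2])
        areas = spm.station_areas
        if areas is None:
            areas = np.ones(len(config))
        m = geometry.compute_metrics(config, areas, ow, nt_rounding=nt_rounding)
        rows.append({"specimen_id": spm.specimen_id, "species": spm.species,
                     "side": spm.side, **m.as_dict()})
        configs.append(config)
    df = pd.DataFrame(rows).set_index("specimen_id").sort_index()
    return df, np.array(configs), [s.species for s in specimens]


def _species_shapes(configs, species, order):
    if order == "joint":
        gpa = shape.procrustes_align(configs)
        shapes, labels = shape.species_consensus(gpa.aligned, species)
    elif order == "consensus_first":
        raw_means, labels = shape.species_consensus(configs, species)
        gpa = shape.procrustes_align(raw_means)
        shapes = gpa.aligned
    else:
        raise ValueError("gpa_order must be 'joint' or 'consensus_first'")
    return shapes, labels, gpa


def _hearing_table(audiograms: list[AudiogramRecord], cfg: PipelineConfig):
    by_species: dict[str, dict[str, AudiogramRecord]] = {}
    for rec in audiograms:
        by_species.setdefault(rec.species, {})[rec.method] = rec
    # reference species: both a speaker-based behavioral and an ABR record
    refs = sorted(sp for sp, recs in by_species.items()
                  if "BA-S" in recs and "ABR" in recs)
    factors = None
    if len(refs) >= 2:
        a, b = refs[0], refs[1]
        factors = audiometry.compute_correction_factors(
            by_species[a]["BA-S"], by_species[a]["ABR"],
            by_species[b]["BA-S"], by_species[b]["ABR"])
    rows = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        rec = recs.get("BA-S") or recs.get("BA-H") or recs.get("ABR")
        hv = audiometry.extract_all(
            rec, factors=factors, criterion=cfg.cutoff_criterion,
            extrapolation_floor=cfg.extrapolation_floor)
        provenance = "corrected" if rec.method == "ABR" else "measured"
        rows.append({"species": sp, **hv.as_dict(), "provenance": provenance})
    df = pd.DataFrame(rows).set_index("species").sort_index()
    fac_df = None
    if factors is not None:
        fac_df = pd.DataFrame({"frequency_khz": factors.frequencies_khz,
                               "factor_db": factors.factors_db})
    return df, fac_df, refs


def _transform_hearing(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for var in FREQ_HEARING_VARS:
        out[var] = np.log2(out[var].astype(float))
    return out


def _grid_fit(y: pd.Series, X: pd.DataFrame, C: np.ndarray,
              species: list[str], min_n: int = 8):
    """One PGLS cell with listwise deletion; returns dict or None."""
    data = pd.concat([y.rename("_y"), X], axis=1).dropna()
    data = data.loc[[s for s in species if s in data.index]]
    n = len(data)
    if n < max(min_n, X.shape[1] + 3):
        return None
    idx = [species.index(s) for s in data.index]
    Csub = C[np.ix_(idx, idx)]
    try:
        fit = pgls_fit(data["_y"].to_numpy(), data.drop(columns="_y").to_numpy(),
                       Csub, predictors=list(X.columns))
    except ValueError:
        return None
    return {"r2": fit.r2, "p": fit.p_f, "n": fit.n,
            "slope": fit.coef[1] if len(fit.coef) == 2 else np.nan}


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    t0 = time.perf_counter()
    log = [f"seed={cfg.seed} config_hash={cfg.hash()}"]
    world = None
    if cfg.synthetic is not None:
        world = generate_world(cfg.synthetic, cfg.seed)
        specimens, phy, audiograms, traits = _from_world(world)
        log.append(f"generated synthetic world: {len(specimens)} specimens, "
                   f"{phy.n_tips} species")
    else:
        specimens, phy, audiograms, traits = _load_real(cfg)
        log.append(f"loaded {len(specimens)} specimens, {phy.n_tips} tree tips")

    missing = sorted({s.species for s in specimens} - set(phy.tip_labels))
    if missing:
        raise ValueError(f"species present in landmarks but absent from tree: {missing}")

    metrics_spec, configs, spec_species = _specimen_metrics(specimens, cfg.nt_rounding)
    log.append(f"metrics computed for {len(metrics_spec)} specimens")

    shapes, labels, gpa = _species_shapes(configs, spec_species, cfg.gpa_order)
    log.append(f"GPA converged={gpa.converged} iterations={gpa.iterations}")

    pca = shape.shape_pca(shapes, labels)
    ppca = shape.phylo_pca(shapes, labels, phy)
    n_pc = min(3, pca.scores.shape[1])
    scores = pd.DataFrame(
        pca.scores[:, :10], index=pd.Index(labels, name="species"),
        columns=[f"PC{i+1}" for i in range(min(10, pca.scores.shape[1]))])
    pscores = pd.DataFrame(
        ppca.scores[:, :10], index=pd.Index(ppca.labels, name="species"),
        columns=[f"pPC{i+1}" for i in range(min(10, ppca.scores.shape[1]))])
    var_rows = [{"component": f"PC{i+1}",
                 "variance_fraction": float(pca.variance_fractions[i]),
                 "ppca_variance_fraction": float(ppca.variance_fractions[i])}
                for i in range(min(10, len(pca.variance_fractions)))]

    # phylogenetic signal on PC1..PC3 and Kmult on their joint scores
    sig_rows = []
    for i in range(n_pc):
        res = blomberg_k(pca.scores[:, i], phy, n_perm=cfg.n_perm,
                         seed=cfg.seed + 101 + i)
        sig_rows.append({"trait": f"PC{i+1}", "statistic": "K",
                         "value": res.statistic, "p": res.p,
                         "n_perm": res.n_perm})
    resm = kmult(pca.scores[:, :n_pc], phy, n_perm=cfg.n_perm,
                 seed=cfg.seed + 100)
    sig_rows.append({"trait": f"PC1-{n_pc}", "statistic": "Kmult",
                     "value": resm.statistic, "p": resm.p, "n_perm": resm.n_perm})
    log.append("phylogenetic signal computed")

    hearing, factors_df, refs = _hearing_table(audiograms, cfg)
    log.append(f"hearing variables for {len(hearing)} species "
               f"(correction references: {refs})")

    # species-mean metrics, then log10 on everything except CSR
    mm = metrics_spec.groupby("species")[list(MORPH_VARS)].mean().sort_index()
    morph = mm.copy()
    for var in MORPH_VARS:
        if var != "CSR":
            morph[var] = np.log10(morph[var])
    morph = morph.join(np.log10(
        traits[["body_mass_g", "interaural_mm"]]
    ).rename(columns={"body_mass_g": "log_mass", "interaural_mm": "log_iad"}))
    groups = traits["group"] if "group" in traits.columns else pd.Series(
        "all", index=traits.index)

    C = bm_covariance(phy).matrix
    species_order = phy.tip_labels
    morph = morph.loc[[s for s in species_order if s in morph.index]]
    hearing_t = _transform_hearing(hearing)
    for var, excluded in (cfg.exclusions or {}).items():
        if var in hearing_t.columns:
            hearing_t.loc[hearing_t.index.isin(excluded), var] = np.nan
            log.append(f"excluded {excluded} from {var} fits")

    group_sets = {"all": list(morph.index)}
    for g in sorted(groups.unique()):
        group_sets[g] = sorted(groups[groups == g].index)
    if {"Myomorpha", "SH"} <= set(group_sets):
        group_sets["Rodentia"] = sorted(group_sets["Myomorpha"] + group_sets["SH"])

    pc_sets = {"PC1+PC2+PC3": [f"PC{i+1}" for i in range(n_pc)]}
    for i in range(n_pc):
        pc_sets[f"PC{i+1}"] = [f"PC{i+1}"]

    # --- Table-2-style grid: shape PCs predicting each morphological var
    grid_rows = []
    for set_name, cols in pc_sets.items():
        X = scores[cols]
        for var in list(MORPH_VARS) + ["log_mass"]:
            cell = _grid_fit(morph[var], X, C, species_order)
            if cell is None:
                grid_rows.append({"predictors": set_name, "response": var,
                                  "r2": np.nan, "p": np.nan, "n": 0})
            else:
                grid_rows.append({"predictors": set_name, "response": var,
                                  "r2": cell["r2"], "p": cell["p"],
                                  "n": cell["n"]})

    # --- morphology ~ body mass, overall and per group
    mass_rows = []
    for gname, members in sorted(group_sets.items()):
        sub = [s for s in species_order if s in members]
        for var in MORPH_VARS:
            cell = _grid_fit(morph[var].loc[morph.index.isin(sub)],
                             morph[["log_mass"]], C, species_order)
            if cell is not None:
                mass_rows.append({"group": gname, "response": var,
                                  "r2": cell["r2"], "p": cell["p"],
                                  "slope": cell["slope"], "n": cell["n"]})

    # --- hearing ~ shape / morphology, overall and per group
    hear_rows = []
    predictor_cols = {**{k: v for k, v in pc_sets.items()}}
    single_morphs = {var: [var] for var in MORPH_VARS}
    for gname, members in sorted(group_sets.items()):
        sub = set(members)
        for hv in HEARING_VARS:
            y_all = hearing_t[hv].astype(float)
            y = y_all.where(y_all.index.isin(sub))
            for pname, cols in predictor_cols.items():
                cell = _grid_fit(y, scores[cols], C, species_order)
                if cell is not None:
                    hear_rows.append({"group": gname, "response": hv,
                                      "predictors": pname, "r2": cell["r2"],
                                      "p": cell["p"], "n": cell["n"]})
            for pname, cols in single_morphs.items():
                cell = _grid_fit(y, morph[cols], C, species_order)
                if cell is not None:
                    hear_rows.append({"group": gname, "response": hv,
                                      "predictors": pname, "r2": cell["r2"],
                                      "p": cell["p"], "n": cell["n"]})
            for pname in ("log_mass", "log_iad"):
                cell = _grid_fit(y, morph[[pname]], C, species_order)
                if cell is not None:
                    hear_rows.append({"group": gname, "response": hv,
                                      "predictors": pname, "r2": cell["r2"],
                                      "p": cell["p"], "n": cell["n"]})
    log.append(f"PGLS grids: {len(grid_rows) + len(mass_rows) + len(hear_rows)} cells")

    # --- Mann-Whitney group comparisons on CL and CW (primates vs rodents)
    mw_rows = []
    if "Primates" in group_sets and "Rodentia" in group_sets:
        for var in ("CL", "CW", "NT", "OWA"):
            a = mm[var].loc[mm.index.isin(group_sets["Primates"])].dropna()
            b = mm[var].loc[mm.index.isin(group_sets["Rodentia"])].dropna()
            if len(a) >= 2 and len(b) >= 2:
                u, p = mann_whitney_u(a.to_numpy(), b.to_numpy())
                mw_rows.append({"variable": var, "group_a": "Primates",
                                "group_b": "Rodentia", "U": u, "p": p,
                                "n_a": len(a), "n_b": len(b)})

    # --- ancestral states of PC1
    pc1 = scores["PC1"].loc[species_order].to_numpy()
    est, var, _ = ancestral_states(pc1, phy)
    anc = pd.DataFrame({"node": list(est.keys()),
                        "pc1_estimate": list(est.values()),
                        "variance": [var[k] for k in est]}).set_index("node")

    tables = {
        "metrics_specimen": metrics_spec,
        "metrics_species": mm,
        "morphology_log": morph,
        "hearing_variables": hearing,
        "pca_scores": scores,
        "ppca_scores": pscores,
        "variance_fractions": pd.DataFrame(var_rows).set_index("component"),
        "phylogenetic_signal": pd.DataFrame(sig_rows).set_index("trait"),
        "pgls_shape_morphology": pd.DataFrame(grid_rows),
        "pgls_body_mass": pd.DataFrame(mass_rows),
        "pgls_hearing": pd.DataFrame(hear_rows),
        "group_tests": pd.DataFrame(mw_rows),
        "ancestral_pc1": anc,
    }
    if factors_df is not None:
        tables["correction_factors"] = factors_df
    log.append(f"done in {time.perf_counter() - t0:.1f} s")
    bundle = ResultsBundle(tables, log, cfg.hash(), cfg.seed)
    if cfg.outdir:
        bundle.write(cfg.outdir)
    return bundle
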