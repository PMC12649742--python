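"""End-to-end pipeline: simulate -> decompose -> regress -> screen ->
reconstruct -> OBI -> nested ANOVA.

The stage order mirrors the analysis workflow: a cohort of subject-
hemisphere connectivity matrices is generated (or loaded), matrices are
mirrored into a canonical left-indexed frame and averaged within
species, each species average is factorized at every requested K,
connection components are screened and anatomically filtered on the
group gray factors, subject-level factors are obtained by dual
regression, per-subject connection reconstructions yield OBI records,
and the species/hemisphere/K hierarchy of OBI values is partitioned by
nested ANOVA with Bonferroni post-hocs.

All randomness derives from the single config seed; rerunning an
identical config reproduces every table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .anova import NestedAnovaResult, NestedDataset, nested_anova, \
    posthoc_bonferroni
from .errors import InvalidSpecError
from .match import best_match_table
from .nmf import Decomposition, dual_regress, fit_group_nmf
from .obi import MaskSet, obi_table
from .select import FilterThresholds, anatomical_filter, merge_components, \
    screening_scores, zero_contralateral
from .synthetic import CohortGeometry, CohortSpec, ConnectivityMatrix, \
    NoiseModel, SpeciesSpec, make_bundles, make_cohort, make_geometry, \
    mirror_to_canonical

__version__ = "0.1.0"

_SCREEN_ROI_A = {"ATF": "TEMPORAL_POLE", "OTF": "OCCIPITAL"}


@dataclass
class PipelineConfig:
    """Serializable description of a full pipeline run."""

    # geometry
    n_vertices: int = 2000
    n_voxels: int = 3000
    parcel_fractions: dict | None = None
    # cohort
    species: list = field(default_factory=lambda: [
        {"name": "macaque_like", "n_subjects": 3,
         "atf_ofc_fraction": 0.38, "otf_ofc_fraction": 0.29},
        {"name": "squirrel_like", "n_subjects": 3,
         "atf_ofc_fraction": 0.47, "otf_ofc_fraction": 0.32},
        {"name": "lemur_like", "n_subjects": 3,
         "atf_ofc_fraction": 0.93, "otf_ofc_fraction": 0.77},
    ])
    hemisphere_sd: float = 0.2
    noise_kind: str = "POISSON"
    noise_scale: float = 1.0
    subject_gain: float = 50.0
    gain_sd: float = 0.2
    n_distractors: int = 6
    bundle_width: float = 0.08
    # decomposition
    k_list: list = field(default_factory=lambda: [4, 8, 12, 16])
    nmf_tol: float = 1e-6
    nmf_max_iter: int = 500
    # selection
    parietal_max: float = 0.10
    occipital_max: float = 0.10
    endpoint_min: float = 0.15
    axis_cone_deg: float = 30.0
    screen_top_n: int = 5
    screen_mad_factor: float = 2.0
    # statistics
    obi_denominator: str = "pfc"
    posthoc_pool: str = "observations"
    posthoc_variant: str = "welch"
    # stages
    match_references: bool = True
    write_outputs: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.k_list or any(k < 1 for k in self.k_list):
            raise InvalidSpecError("k_list must be nonempty with all K >= 1")

    # -- serialization (lossless round trip) --
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- builders --
    def build_geometry(self) -> CohortGeometry:
        return make_geometry(self.n_vertices, self.n_voxels,
                             self.parcel_fractions, seed=self.seed)

    def build_cohort_spec(self) -> CohortSpec:
        species = tuple(
            SpeciesSpec(s["name"], s["n_subjects"],
                        {"ATF": s["atf_ofc_fraction"],
                         "OTF": s["otf_ofc_fraction"]})
            for s in self.species)
        return CohortSpec(species_list=species,
                          hemisphere_sd=self.hemisphere_sd,
                          noise_model=NoiseModel(self.noise_kind,
                                                 self.noise_scale),
                          subject_gain=self.subject_gain,
                          gain_sd=self.gain_sd,
                          n_distractors=self.n_distractors,
                          bundle_width=self.bundle_width,
                          seed=self.seed)

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(self.parietal_max, self.occipital_max,
                                self.endpoint_min, self.axis_cone_deg)


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: dict
    obi_records: pd.DataFrame
    anova: dict  # class -> NestedAnovaResult (or None)
    posthoc: dict  # class -> DataFrame (or None)
    match_table: pd.DataFrame | None
    manifest: dict
    decompositions: dict  # (species, K) -> Decomposition
    selection: dict  # (species, K, class) -> dict diagnostics


def species_average(matrices: list[ConnectivityMatrix],
                    geometry: CohortGeometry) -> dict[str, np.ndarray]:
    """Arithmetic mean of subject matrices per species in the canonical
    left-indexed frame (RIGHT hemispheres mirrored before averaging)."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for m in matrices:
        canon = mirror_to_canonical(m.values, geometry, m.hemisphere)
        if m.species not in sums:
            sums[m.species] = canon.astype(float).copy()
            counts[m.species] = 1
        else:
            sums[m.species] += canon
            counts[m.species] += 1
    return {sp: sums[sp] / counts[sp] for sp in sums}


def _nmf_seed(base_seed: int, species: str, K: int) -> int:
    return (base_seed * 1000003 + zlib.crc32(f"{species}:{K}".encode())) % (2 ** 31)


def select_connection_members(decomp: Decomposition,
                              geometry: CohortGeometry,
                              connection_class: str,
                              thresholds: FilterThresholds,
                              top_n: int = 5, mad_factor: float = 2.0
                              ) -> tuple[list[int], dict]:
    """Screen and anatomically filter group components for one
    connection class in the canonical (LEFT) frame.

    Returns the member component indices to merge plus diagnostics. If
    no screened component survives the anatomical filter, the
    top-scoring screened component is used as a fallback (recorded in
    the diagnostics) so a reconstruction is always available.
    """
    roi_a = geometry.vertices_of(_SCREEN_ROI_A[connection_class], "LEFT")
    roi_b = geometry.vertices_of(("OFC", "PFC_OTHER"), "LEFT")
    H_zeroed = np.vstack([
        zero_contralateral(row, geometry.hemisphere_of, "LEFT")
        for row in decomp.H])
    screen = screening_scores(H_zeroed, roi_a, roi_b, top_n=top_n,
                              mad_factor=mad_factor)
    selected = [s.component_id for s in screen if s.selected]
    members, filter_diags = [], {}
    for i in selected:
        ok, d = anatomical_filter(H_zeroed[i], decomp.W[:, i], geometry,
                                  connection_class, thresholds)
        filter_diags[i] = d
        if ok:
            members.append(i)
    fallback = False
    if not members and selected:
        best = max(selected, key=lambda i: screen[i].product_score)
        members = [best]
        fallback = True
    diagnostics = {
        "screen": [dataclasses.asdict(s) for s in screen],
        "selected": selected,
        "members": members,
        "fallback_used": fallback,
        "filter": filter_diags,
    }
    return members, diagnostics


def default_mask_sets(geometry: CohortGeometry) -> list[MaskSet]:
    """The default OFC-in-PFC mask pair in the canonical LEFT frame."""
    return [MaskSet("default",
                    geometry.vertices_of("OFC", "LEFT"),
                    geometry.vertices_of(("OFC", "PFC_OTHER"), "LEFT"))]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 resume: bool = False) -> PipelineResult:
    """Execute the full pipeline for one configuration.

    When ``out_dir`` is given (and ``config.write_outputs``), matrices,
    factor tables, OBI records, ANOVA results, the report and a hashed
    run manifest are written there; with ``resume=True``, decomposition
    stages whose outputs exist and hash-match the manifest are reloaded
    instead of refitted.
    """
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    writing = out is not None and config.write_outputs
    if writing:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config_hash": config.config_hash(),
                      "version": __version__, "stages": {}}
    old_manifest = None
    if out is not None and resume:
        mpath = out / "manifest.json"
        if mpath.exists():
            candidate = json.loads(mpath.read_text())
            if candidate.get("config_hash") == manifest["config_hash"]:
                old_manifest = candidate

    def record_stage(name: str, outputs: dict[str, Path], started: float):
        manifest["stages"][name] = {
            "status": "done",
            "elapsed_s": round(time.time() - started, 3),
            "outputs": {str(p.relative_to(out)): tio.file_hash(p)
                        for p in outputs.values()} if writing else {},
        }

    # ---- stage: simulate ----
    t_stage = time.time()
    geometry = config.build_geometry()
    spec = config.build_cohort_spec()
    matrices, truth = make_cohort(spec, geometry)
    outputs: dict[str, Path] = {}
    if writing:
        outputs["labels"] = tio.write_labels(geometry, out / "labels.tsv")
        outputs["bundles"] = tio.write_bundles(truth, out / "bundles.tsv")
        for m in matrices:
            p = out / "matrices" / f"{m.subject_id}_{m.hemisphere}.mtx"
            outputs[p.name] = tio.write_connectivity(m, p, geometry)
    record_stage("simulate", outputs, t_stage)

    # ---- stage: decompose per species x K ----
    averages = species_average(matrices, geometry)
    decompositions: dict[tuple[str, int], Decomposition] = {}
    for sp_name, V_avg in averages.items():
        for K in config.k_list:
            t_stage = time.time()
            stage = f"decompose_{sp_name}_K{K}"
            w_path = out / "decomp" / f"{sp_name}_K{K}_W.tsv" if out else None
            h_path = out / "decomp" / f"{sp_name}_K{K}_H.tsv" if out else None
            reused = False
            if (old_manifest is not None and w_path is not None
                    and stage in old_manifest["stages"]):
                recorded = old_manifest["stages"][stage]["outputs"]
                try:
                    ok = all(
                        (out / rel).exists()
                        and tio.file_hash(out / rel) == h
                        for rel, h in recorded.items())
                except OSError:
                    ok = False
                if ok and recorded:
                    W = tio.read_matrix_tsv(w_path)
                    H = tio.read_matrix_tsv(h_path)
                    decomp = Decomposition(
                        W=W, H=H, K=K, objective_trace=np.array([]),
                        seed=_nmf_seed(config.seed, sp_name, K),
                        converged=True)
                    reused = True
            if not reused:
                decomp = fit_group_nmf(V_avg, K,
                                       seed=_nmf_seed(config.seed, sp_name, K),
                                       tol=config.nmf_tol,
                                       max_iter=config.nmf_max_iter)
            decompositions[(sp_name, K)] = decomp
            outputs = {}
            if writing:
                outputs["W"] = tio.write_matrix_tsv(decomp.W, w_path)
                outputs["H"] = tio.write_matrix_tsv(decomp.H, h_path)
            record_stage(stage, outputs, t_stage)

    # ---- stage: screen / regress / reconstruct / OBI ----
    t_stage = time.time()
    thresholds = config.thresholds()
    selection: dict = {}
    for (sp_name, K), decomp in decompositions.items():
        for cls in ("ATF", "OTF"):
            members, diag = select_connection_members(
                decomp, geometry, cls, thresholds,
                top_n=config.screen_top_n,
                mad_factor=config.screen_mad_factor)
            selection[(sp_name, K, cls)] = {"members": members, **diag}

    mask_sets = default_mask_sets(geometry)
    connections = []
    for m in matrices:
        canon = mirror_to_canonical(m.values, geometry, m.hemisphere)
        for K in config.k_list:
            decomp = decompositions[(m.species, K)]
            subject = dual_regress(
                ConnectivityMatrix(m.subject_id, m.species, m.hemisphere,
                                   canon), decomp)
            for cls in ("ATF", "OTF"):
                members = selection[(m.species, K, cls)]["members"]
                if not members:
                    continue
                conn = merge_components(
                    [(subject.H_s[i], subject.W_s[:, i]) for i in members],
                    cls, "LEFT", geometry.hemisphere_of,
                    component_ids=members)
                connections.append((conn, {"species": m.species,
                                           "subject_id": m.subject_id,
                                           "hemisphere": m.hemisphere,
                                           "K": K}))
    obi_records = obi_table(connections, mask_sets,
                            denominator=config.obi_denominator)
    outputs = {}
    if writing:
        p = out / "obi.tsv"
        obi_records.to_csv(p, sep="\t", index=False)
        outputs["obi"] = p
    record_stage("obi", outputs, t_stage)

    # ---- stage: nested ANOVA per connection class ----
    t_stage = time.time()
    anova_results: dict = {}
    posthoc_results: dict = {}
    for cls in ("ATF", "OTF"):
        sub = obi_records[obi_records.connection_class == cls].copy()
        if sub.empty or len(config.k_list) < 2:
            anova_results[cls] = None
            posthoc_results[cls] = None
            continue
        sub["subgroup"] = sub.subject_id + "|" + sub.hemisphere
        data = NestedDataset.from_frame(sub, value="obi", group="species",
                                        subgroup="subgroup")
        anova_results[cls] = nested_anova(data)
        posthoc_results[cls] = posthoc_bonferroni(
            data, pool=config.posthoc_pool, variant=config.posthoc_variant)
    outputs = {}
    if writing:
        p = out / "anova.json"
        p.write_text(json.dumps(
            {cls: (r.to_dict() if r is not None else None)
             for cls, r in anova_results.items()}, indent=1))
        outputs["anova"] = p
    record_stage("anova", outputs, t_stage)

    # ---- stage: match against ground-truth reference tracts ----
    match_df = None
    if config.match_references:
        t_stage = time.time()
        frames = []
        for sp in spec.species_list:
            refs = make_bundles(geometry, spec, sp.name, "LEFT")
            ref_whites = [b.white_loading for b in refs]
            ref_ids = [b.bundle_id for b in refs]
            for K in config.k_list:
                decomp = decompositions[(sp.name, K)]
                tbl = best_match_table(
                    [decomp.W[:, i] for i in range(decomp.K)],
                    ref_whites, K=K, reference_ids=ref_ids)
                tbl.insert(0, "species", sp.name)
                frames.append(tbl)
        match_df = pd.concat(frames, ignore_index=True)
        outputs = {}
        if writing:
            p = out / "match.tsv"
            match_df.to_csv(p, sep="\t", index=False)
            outputs["match"] = p
        record_stage("match", outputs, t_stage)

    # ---- report ----
    summary: dict = {}
    ranking: dict = {}
    for cls in ("ATF", "OTF"):
        sub = obi_records[obi_records.connection_class == cls]
        stats = sub.groupby("species")["obi"].agg(["mean", "std", "count"])
        summary[cls] = {sp: {"mean": float(r["mean"]),
                             "sd": float(r["std"]),
                             "n": int(r["count"])}
                        for sp, r in stats.iterrows()}
        ranking[cls] = list(stats["mean"].sort_values(ascending=False).index)
    report = {
        "seed": config.seed,
        "k_list": list(config.k_list),
        "obi_summary": summary,
        "species_ranking": ranking,
        "anova": {cls: (r.to_dict() if r is not None else None)
                  for cls, r in anova_results.items()},
        "posthoc": {cls: (p.to_dict(orient="records") if p is not None
                          else None)
                    for cls, p in posthoc_results.items()},
        "selection_fallbacks": sorted(
            f"{sp}:K{K}:{cls}" for (sp, K, cls), d in selection.items()
            if d["fallback_used"]),
        "elapsed_s": round(time.time() - t0, 3),
    }
    if match_df is not None:
        report["match_mean_best_r"] = {
            sp: {int(k): float(g["best_r"].mean())
                 for k, g in grp.groupby("K")}
            for sp, grp in match_df.groupby("species")}
    if writing:
        (out / "report.json").write_text(json.dumps(report, indent=1))
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=1, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(config=config, report=report,
                          obi_records=obi_records, anova=anova_results,
                          posthoc=posthoc_results, match_table=match_df,
                          manifest=manifest, decompositions=decompositions,
                          selection=selection)
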