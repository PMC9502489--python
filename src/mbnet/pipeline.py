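"""End-to-end orchestration: cohort -> networks -> metrics -> inference.

A run is fully described by a serialisable :class:`RunConfig`; two runs with
the same config produce byte-identical output files. All randomness flows
from one master seed through named substreams, so stages are reproducible
in isolation as well.

Output layout under ``config.out_dir``::

    manifest.json              config echo, versions, seeds, warnings
    cohort/                    covariates.tsv + features.tsv (synthetic mode)
    matrices/<subject>.tsv     per-subject similarity matrices
    metric_curves.tsv          tidy (subject, metric, node, sparsity, value)
    metric_auc.tsv             tidy (subject, metric, node, auc)
    group_tests_global.tsv     permutation tests on global metric AUCs
    group_tests_nodal.tsv      nodal tests with BH-FDR per metric family
    nbs_components.tsv         per-component NBS summary, both directions
    nbs_edges.tsv              suprathreshold edge lists (viewer-friendly)
    correlations.tsv           partial correlations with clinical variables
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mbnet import cohort as cohort_mod
from mbnet import inference, metrics, network
from mbnet.cohort import COVARIATE_COLUMNS, CohortSpec

__all__ = ["RunConfig", "run_pipeline", "cohort_aucs"]

CLINICAL_VARIABLES = ("off_therapy_years", "IQ", "TMT_A", "DST")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    mode: str = "synthetic"  # "synthetic" | "tabular"
    cohort_spec: CohortSpec | None = None
    input_dir: str | None = None  # tabular mode: dir with covariates.tsv/features.tsv
    out_dir: str = "mbnet_run"
    sparsity_min: float = 0.05
    sparsity_max: float = 0.40
    sparsity_step: float = 0.01
    n_nulls: int = 100
    n_perm: int = 1000
    primary_p: float = 0.05
    fdr_q: float = 0.05
    node_subset: list | None = None  # NBS restriction; None = all regions
    small_world: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("synthetic", "tabular"):
            raise ValueError(f"mode must be 'synthetic' or 'tabular', got {self.mode!r}")
        if self.mode == "synthetic" and self.cohort_spec is None:
            self.cohort_spec = CohortSpec(seed=self.seed)
        if self.mode == "tabular" and not self.input_dir:
            raise ValueError("tabular mode requires input_dir")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        spec = d.get("cohort_spec")
        if isinstance(spec, dict):
            spec = dict(spec)
            if isinstance(spec.get("base_model"), dict):
                spec["base_model"] = cohort_mod.BaseModel(**spec["base_model"])
            if isinstance(spec.get("covariate_model"), dict):
                cm = dict(spec["covariate_model"])
                for key in ("age_range", "off_therapy_range"):
                    if key in cm and cm[key] is not None:
                        cm[key] = tuple(cm[key])
                spec["covariate_model"] = cohort_mod.CovariateModel(**cm)
            for key in ("vertices_per_region", "effect_regions"):
                if key in spec and spec[key] is not None:
                    spec[key] = tuple(spec[key])
            d["cohort_spec"] = CohortSpec(**spec)
        return cls(**d)

    def sparsities(self) -> np.ndarray:
        return metrics.sparsity_grid(self.sparsity_min, self.sparsity_max, self.sparsity_step)


def sub_seed(master: int, *key: int) -> int:
    """Deterministic named substream seed below 2**31."""
    ss = np.random.SeedSequence(entropy=[int(master)] + [int(k) for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def cohort_aucs(cohort, sparsities, n_nulls=100, seed=0, small_world=True, betweenness=True):
    """Similarity matrices, metric curves and AUC tables for a whole cohort.

    Returns ``(matrices, curves_by_subject, auc_long)`` where ``auc_long``
    is a tidy DataFrame (subject_id, group, metric, node, auc) with node
    "global" for scalar metrics.
    """
    mats, curves_by_subject, rows = [], {}, []
    for i, subj in enumerate(cohort):
        sm = network.similarity_matrix(subj)
        mats.append(sm)
        curves = metrics.sweep_metrics(
            sm,
            sparsities,
            n_nulls=n_nulls,
            seed=sub_seed(seed, 1, i),
            small_world=small_world,
            betweenness=betweenness,
        )
        curves_by_subject[subj.subject_id] = curves
        for name, curve in curves.items():
            auc = curve.auc
            if np.ndim(auc) == 0:
                rows.append((subj.subject_id, subj.group, name, "global", float(auc)))
            else:
                for rid, v in zip(sm.region_ids, auc):
                    rows.append((subj.subject_id, subj.group, name, str(rid), float(v)))
    auc_long = pd.DataFrame(rows, columns=["subject_id", "group", "metric", "node", "auc"])
    return mats, curves_by_subject, auc_long


def _group_tests(auc_long, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    glob_rows, nodal_frames = [], []
    is_a = auc_long["group"] == "A"
    for j, metric_name in enumerate(metrics.GLOBAL_METRICS):
        sub = auc_long[auc_long["metric"] == metric_name]
        if sub.empty:
            continue
        a = sub[sub["group"] == "A"]["auc"].to_numpy()
        b = sub[sub["group"] == "B"]["auc"].to_numpy()
        res = inference.permutation_test_auc(
            a, b, n_perm=config.n_perm, seed=sub_seed(config.seed, 2, j), metric=metric_name
        )
        glob_rows.append(dataclasses.asdict(res))
    global_df = pd.DataFrame(glob_rows)

    for j, metric_name in enumerate(metrics.NODAL_METRICS):
        sub = auc_long[auc_long["metric"] == metric_name]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="subject_id", columns="node", values="auc", sort=False)
        groups = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
        A = wide.loc[groups[groups == "A"].index].to_numpy()
        B = wide.loc[groups[groups == "B"].index].to_numpy()
        results = inference.permutation_test_auc_table(
            A, B, n_perm=config.n_perm, seed=sub_seed(config.seed, 3, j),
            metric=metric_name, nodes=list(wide.columns),
        )
        df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        # one FDR family per nodal metric (one test per region)
        reject, padj = inference.fdr_bh(df["p"].to_numpy(), q=config.fdr_q)
        df["fdr_q"] = padj
        df["significant"] = reject
        nodal_frames.append(df)
    nodal_df = pd.concat(nodal_frames, ignore_index=True) if nodal_frames else pd.DataFrame()
    return global_df, nodal_df


def _correlations(cohort, auc_long, nodal_df, config) -> pd.DataFrame:
    """Partial correlations of significant nodal AUCs with clinical scores.

    Run within group B (the clinical group: off-therapy duration only exists
    there), controlling age and sex; BH-FDR over the whole correlation
    family.
    """
    if nodal_df.empty:
        return pd.DataFrame()
    sig = nodal_df[nodal_df["significant"]]
    if sig.empty:
        return pd.DataFrame()
    subjects_b = [s for s in cohort if s.group == "B"]
    if len(subjects_b) < 5:
        return pd.DataFrame()
    sid_b = [s.subject_id for s in subjects_b]
    cov = pd.DataFrame(
        {
            "age": [s.covariates.get("age", np.nan) for s in subjects_b],
            "sex": [s.covariates.get("sex", np.nan) for s in subjects_b],
        },
        index=sid_b,
    )
    clin = {
        v: np.array([s.covariates.get(v, np.nan) for s in subjects_b]) for v in CLINICAL_VARIABLES
    }
    rows = []
    for _, srow in sig.iterrows():
        sub = auc_long[
            (auc_long["metric"] == srow["metric"])
            & (auc_long["node"] == srow["node"])
            & (auc_long["subject_id"].isin(sid_b))
        ].set_index("subject_id")["auc"]
        x = sub.reindex(sid_b).to_numpy()
        for var, y in clin.items():
            if np.sum(np.isfinite(y)) < 5:
                continue
            res = inference.partial_correlation(
                x, y, cov, x_name=f"{srow['metric']}[{srow['node']}]", y_name=var
            )
            rows.append(dataclasses.asdict(res))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    reject, padj = inference.fdr_bh(df["p"].to_numpy(), q=config.fdr_q)
    df["fdr_q"] = padj
    df["significant"] = reject
    df["covariates"] = df["covariates"].map(lambda c: ",".join(map(str, c)))
    return df


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all result files.

    Returns a dict with the in-memory results (matrices, AUC table, test
    tables, NBS results, manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if config.mode == "synthetic":
            cohort = cohort_mod.simulate_cohort(config.cohort_spec)
            cohort_mod.write_cohort(cohort, out / "cohort")
        else:
            cohort = cohort_mod.read_cohort(config.input_dir)
        if not cohort:
            raise RuntimeError("stage cohort: empty cohort")

        sparsities = config.sparsities()
        mats, curves_by_subject, auc_long = cohort_aucs(
            cohort, sparsities, n_nulls=config.n_nulls, seed=config.seed,
            small_world=config.small_world,
        )
        mat_dir = out / "matrices"
        mat_dir.mkdir(exist_ok=True)
        for sm in mats:
            network.write_similarity_tsv(sm, mat_dir / f"{sm.subject_id}.tsv")

        curve_rows = []
        for sid, curves in curves_by_subject.items():
            for name, curve in curves.items():
                if curve.values.ndim == 1:
                    for s, v in zip(curve.sparsities, curve.values):
                        curve_rows.append((sid, name, "global", float(s), float(v)))
                else:
                    rids = mats[0].region_ids
                    for si, s in enumerate(curve.sparsities):
                        for rid, v in zip(rids, curve.values[si]):
                            curve_rows.append((sid, name, str(rid), float(s), float(v)))
        _write_tsv(
            pd.DataFrame(curve_rows, columns=["subject_id", "metric", "node", "sparsity", "value"]),
            out / "metric_curves.tsv",
        )
        _write_tsv(auc_long, out / "metric_auc.tsv")

        groups = {s.group for s in cohort}
        two_groups = groups >= {"A", "B"}
        global_df = nodal_df = corr_df = pd.DataFrame()
        nbs_results = {}
        if two_groups:
            global_df, nodal_df = _group_tests(auc_long, config)
            _write_tsv(global_df, out / "group_tests_global.tsv")
            _write_tsv(nodal_df, out / "group_tests_nodal.tsv")

            mats_a = [m for m, s in zip(mats, cohort) if s.group == "A"]
            mats_b = [m for m, s in zip(mats, cohort) if s.group == "B"]
            nbs_results = inference.nbs(
                mats_a, mats_b,
                primary_p=config.primary_p, n_perm=config.n_perm,
                seed=sub_seed(config.seed, 4), node_subset=config.node_subset,
            )
            comp_rows, edge_rows = [], []
            for direction, res in nbs_results.items():
                for ci, comp in enumerate(res.components):
                    comp_rows.append(
                        {
                            "direction": direction,
                            "component": ci,
                            "extent": comp.extent,
                            "n_nodes": len(comp.nodes),
                            "p": comp.p,
                            "nodes": ",".join(map(str, comp.nodes)),
                        }
                    )
                    ids = res.node_subset
                    for (ni, nj) in comp.edges:
                        ii, jj = ids.index(ni), ids.index(nj)
                        edge_rows.append(
                            {
                                "direction": direction,
                                "component": ci,
                                "node_i": ni,
                                "node_j": nj,
                                "t": res.edge_t[ii, jj],
                                "p": res.edge_p[ii, jj],
                            }
                        )
            _write_tsv(pd.DataFrame(comp_rows), out / "nbs_components.tsv")
            _write_tsv(pd.DataFrame(edge_rows), out / "nbs_edges.tsv")

            corr_df = _correlations(cohort, auc_long, nodal_df, config)
            _write_tsv(corr_df, out / "correlations.tsv")

        caught = sorted({f"{w.category.__name__}: {w.message}" for w in wlist})

    import mbnet

    manifest = {
        "package": "mbnet",
        "version": mbnet.__version__,
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "n_regions": mats[0].n_regions,
        "groups": sorted(groups),
        "sparsity_grid": [float(s) for s in sparsities],
        "substreams": {
            "metrics": "sub_seed(seed, 1, subject_index)",
            "global_tests": "sub_seed(seed, 2, metric_index)",
            "nodal_tests": "sub_seed(seed, 3, metric_index)",
            "nbs": "sub_seed(seed, 4)",
        },
        "warnings": caught,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "cohort": cohort,
        "matrices": mats,
        "auc": auc_long,
        "global_tests": global_df,
        "nodal_tests": nodal_df,
        "nbs": nbs_results,
        "correlations": corr_df,
        "manifest": manifest,
    }
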