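"""End-to-end orchestration: cohort -> preprocessing -> BGC -> association.

:func:`run_pipeline` consumes either a cohort on disk (manifest + partition
+ metadata tables) or an in-memory synthetic cohort, runs every subject
through motion scrubbing, nuisance regression and FC estimation, computes
the connectivity summaries, scores and normalizes the symptom measure, and
assembles the full results surface:

* the primary network-level BGC-symptom association table (BH-FDR over the
  networks),
* the region-level table (BH-FDR over the regions, a separate family),
* a Spearman robustness table on raw totals,
* the age/gender-residualized rerun,
* within-network FC associations and the Fisher-z comparison of the
  within- vs between-network correlation for the focus networks,
* the connection-exclusion control (BGC recomputed with the focus
  networks' mutual connections removed) and the pairwise between-network
  mean-FC associations,
* rank-based partial correlations of the three CES-D factors,
* Box-Cox / KS normality diagnostics and a per-subject scrubbing summary,
* an optional rerun under an alternate network partition.

Everything is deterministic given the configuration (including its seed),
and all tables serialize to delimited text with a fixed float format, so a
repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as nio
from .connectivity import (
    NetworkPartition,
    bgc_excluding,
    bgc_profile,
    between_network_fc,
    fc_matrix,
    within_network_fc,
)
from .preprocess import regress_nuisance, scrub
from .stats import (
    association_table,
    compare_correlations,
    correlation_test,
    partial_rank_correlation,
    residualize,
)
from .symptoms import (
    DEFAULT_FACTOR_MAP,
    DEFAULT_REVERSE_ITEMS,
    boxcox_normalize,
    laterality_quotient,
    score_cesd,
)
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one analysis run; round-trips losslessly through YAML."""

    manifest: Optional[str] = None
    partition: Optional[str] = None
    alt_partition: Optional[str] = None
    metadata: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    tr: Optional[float] = None
    scrub_threshold: float = 0.3
    fd_cutoff_hz: float = 0.3
    rotation_radius: float = 50.0
    n_before: int = 1
    n_after: int = 2
    min_retained_frames: int = 200
    reverse_items: tuple = DEFAULT_REVERSE_ITEMS
    factor_map: Mapping = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FACTOR_MAP.items()}
    )
    covariates: tuple = ("age", "gender")
    fdr_q: float = 0.05
    a_priori_network: str = "Fronto-parietal"
    exclusion_networks: Optional[tuple] = None
    boxcox_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.scrub_threshold <= 0:
            raise ValueError("scrub_threshold must be positive")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.manifest is None and self.simulation is None:
            raise ValueError("need either a manifest or a simulation config")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reverse_items"] = list(self.reverse_items)
        d["factor_map"] = {k: list(v) for k, v in self.factor_map.items()}
        d["covariates"] = list(self.covariates)
        if self.exclusion_networks is not None:
            d["exclusion_networks"] = list(self.exclusion_networks)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "reverse_items" in d:
            d["reverse_items"] = tuple(d["reverse_items"])
        if "factor_map" in d:
            d["factor_map"] = {k: tuple(v) for k, v in d["factor_map"].items()}
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        if d.get("exclusion_networks") is not None:
            d["exclusion_networks"] = tuple(d["exclusion_networks"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AnalysisReport:
    network_associations: pd.DataFrame
    region_associations: pd.DataFrame
    spearman_associations: pd.DataFrame
    residualized_associations: pd.DataFrame
    within_network_associations: pd.DataFrame
    exclusion_associations: pd.DataFrame
    between_network_fc_associations: pd.DataFrame
    factor_partial_correlations: pd.DataFrame
    correlation_comparisons: pd.DataFrame
    normality_diagnostics: pd.DataFrame
    scrub_summary: pd.DataFrame
    alt_network_associations: Optional[pd.DataFrame]
    focus_networks: tuple
    n_subjects: int
    provenance: dict

    def tables(self) -> dict:
        out = {
            "network_associations": self.network_associations,
            "region_associations": self.region_associations,
            "spearman_associations": self.spearman_associations,
            "residualized_associations": self.residualized_associations,
            "within_network_associations": self.within_network_associations,
            "exclusion_associations": self.exclusion_associations,
            "between_network_fc_associations": self.between_network_fc_associations,
            "factor_partial_correlations": self.factor_partial_correlations,
            "correlation_comparisons": self.correlation_comparisons,
            "normality_diagnostics": self.normality_diagnostics,
            "scrub_summary": self.scrub_summary,
        }
        if self.alt_network_associations is not None:
            out["alt_network_associations"] = self.alt_network_associations
        return out

    def save(self, outdir: str | Path) -> None:
        write_report(self, outdir)


def _load_subject_arrays(cohort_dir: Path, row) -> tuple:
    paths = {}
    for key in ("timeseries_path", "motion_path", "nuisance_path"):
        p = cohort_dir / row[key]
        if not p.exists():
            raise FileNotFoundError(
                f"subject {row['subject_id']}: missing file {p}"
            )
        paths[key] = p
    return paths


def _gender_indicator(values: pd.Series) -> np.ndarray:
    levels = sorted(set(values))
    if len(levels) > 2:
        raise ValueError(f"gender has more than two levels: {levels}")
    return values.map({lev: i for i, lev in enumerate(levels)}).to_numpy(float)


def _covariate_matrix(meta: pd.DataFrame, names) -> np.ndarray:
    cols = []
    for name in names:
        if name == "gender":
            cols.append(_gender_indicator(meta["gender"]))
        else:
            cols.append(meta[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(meta), 0))


def run_pipeline(
    config: PipelineConfig, cohort: SyntheticCohort | None = None
) -> AnalysisReport:
    """Execute the full analysis and return the assembled report."""
    # ---- inputs -----------------------------------------------------------
    alt_partition = None
    if cohort is None and config.manifest is None:
        cohort = simulate_cohort(config.simulation)
    if cohort is not None:
        partition = cohort.partition
        meta = cohort.metadata.copy()
        tr = cohort.config.tr
        subject_iter = [
            (s.subject_id, s.timeseries, s.motion, s.nuisance)
            for s in cohort.subjects
        ]
    else:
        manifest_path = Path(config.manifest)
        cohort_dir = manifest_path.parent
        manifest = nio.read_manifest(manifest_path)
        if config.partition is None:
            raise ValueError("a partition table is required with a manifest")
        partition = nio.read_partition(config.partition)
        meta_path = config.metadata or cohort_dir / "metadata.tsv"
        meta = nio.read_metadata(meta_path)
        tr = config.tr
        if tr is None:
            sidecar = cohort_dir / "cohort.yaml"
            if sidecar.exists():
                with open(sidecar) as fh:
                    tr = float(yaml.safe_load(fh)["tr"])
        if tr is None:
            raise ValueError("tr not given and no cohort.yaml sidecar found")
        subject_iter = []
        for _, row in manifest.iterrows():
            paths = _load_subject_arrays(cohort_dir, row)
            ts = nio.read_timeseries(
                paths["timeseries_path"], tr, row["subject_id"]
            )
            subject_iter.append(
                (
                    row["subject_id"],
                    ts,
                    nio.read_motion(paths["motion_path"]),
                    nio.read_nuisance(paths["nuisance_path"]),
                )
            )
    if config.alt_partition is not None:
        alt_partition = nio.read_partition(config.alt_partition)

    # ---- per-subject preprocessing and connectivity -----------------------
    kept_ids: list = []
    fcs: list = []
    scrub_rows: list = []
    net_bgc: dict = {net: [] for net in partition.networks}
    within: dict = {net: [] for net in partition.networks}
    region_rows: list = []
    alt_net_bgc: dict = (
        {net: [] for net in alt_partition.networks} if alt_partition else {}
    )
    for sid, ts, motion, nuisance in subject_iter:
        if tuple(ts.region_ids) != tuple(partition.region_ids):
            raise ValueError(
                f"subject {sid}: region order does not match the partition"
            )
        sr = scrub(
            motion,
            ts.tr,
            threshold=config.scrub_threshold,
            cutoff_hz=config.fd_cutoff_hz,
            rotation_radius=config.rotation_radius,
            n_before=config.n_before,
            n_after=config.n_after,
        )
        n_retained = int(sr.keep_mask.sum())
        dropped = n_retained < config.min_retained_frames
        scrub_rows.append(
            (
                sid,
                ts.n_frames,
                sr.n_censored,
                n_retained,
                float(sr.fd_raw.mean()),
                dropped,
            )
        )
        if dropped:
            warnings.warn(
                f"subject {sid} dropped: {n_retained} retained frames "
                f"< floor {config.min_retained_frames}"
            )
            continue
        clean = regress_nuisance(
            ts,
            motion,
            nuisance["ventricle"].to_numpy(),
            nuisance["white_matter"].to_numpy(),
            nuisance["global"].to_numpy(),
            sr.keep_mask,
        )
        fc = fc_matrix(clean.data, clean.region_ids)
        prof = bgc_profile(fc, partition)
        kept_ids.append(sid)
        fcs.append(fc)
        region_rows.append(prof.region_bgc)
        for net in partition.networks:
            net_bgc[net].append(prof.network_bgc[net])
            within[net].append(within_network_fc(fc, partition, net))
        if alt_partition is not None:
            alt_prof = bgc_profile(fc, alt_partition)
            for net in alt_partition.networks:
                alt_net_bgc[net].append(alt_prof.network_bgc[net])

    if not kept_ids:
        raise ValueError("all subjects were dropped during scrubbing")
    meta = meta.set_index("subject_id").loc[kept_ids].reset_index()
    n = len(kept_ids)

    net_df = pd.DataFrame(net_bgc, index=kept_ids).T
    within_df = pd.DataFrame(within, index=kept_ids).T
    region_df = pd.DataFrame(
        np.asarray(region_rows).T, index=list(partition.region_ids), columns=kept_ids
    )

    # ---- symptom scoring and normalization --------------------------------
    item_cols = [f"cesd_{i:02d}" for i in range(1, 21)]
    totals = np.empty(n)
    factor_raw = {name: np.empty(n) for name in config.factor_map}
    for j, (_, row) in enumerate(meta.iterrows()):
        scores = score_cesd(
            row[item_cols].to_numpy(dtype=int),
            config.reverse_items,
            config.factor_map,
        )
        totals[j] = scores.total
        for name in factor_raw:
            factor_raw[name][j] = scores.factors[name]
    hand_cols = [f"hand_{i:02d}" for i in range(1, 12)]
    if set(hand_cols) <= set(meta.columns):
        meta["lq"] = [
            laterality_quotient(row[hand_cols].tolist())
            for _, row in meta.iterrows()
        ]

    bc_total = boxcox_normalize(totals, config.boxcox_shift)
    diag_rows = [
        (
            "cesd_total",
            bc_total.lmbda,
            bc_total.ks_p_before,
            bc_total.ks_p_after,
        )
    ]
    for name, vals in factor_raw.items():
        bc = boxcox_normalize(vals, config.boxcox_shift)
        diag_rows.append((name, bc.lmbda, bc.ks_p_before, bc.ks_p_after))
    normality = pd.DataFrame(
        diag_rows, columns=["measure", "boxcox_lambda", "ks_p_before", "ks_p_after"]
    )
    symptom = bc_total.transformed

    # ---- association tables ----------------------------------------------
    network_assoc = association_table(net_df, symptom, "pearson", fdr=True)
    region_assoc = association_table(region_df, symptom, "pearson", fdr=True)
    spearman_assoc = association_table(net_df, totals, "spearman", fdr=True)
    covs = _covariate_matrix(meta, config.covariates)
    resid_symptom = residualize(symptom, covs) if covs.shape[1] else symptom
    resid_assoc = association_table(net_df, resid_symptom, "pearson", fdr=True)
    within_assoc = association_table(within_df, symptom, "pearson", fdr=False)

    # focus networks: the configured set, else the a priori network plus the
    # two most negatively associated companions in the primary table
    if config.exclusion_networks is not None:
        focus = tuple(config.exclusion_networks)
    else:
        apriori = config.a_priori_network
        if apriori not in partition.networks:
            apriori = partition.networks[0]
        ranked = (
            network_assoc[network_assoc["unit"] != apriori]
            .sort_values("estimate")["unit"]
            .tolist()
        )
        focus = (apriori, *ranked[:2])

    excl_rows = []
    for net in partition.networks:
        excluded = tuple(f for f in focus if f != net) if net in focus else ()
        vals = np.array(
            [bgc_excluding(fc, partition, net, excluded) for fc in fcs]
        )
        res = correlation_test(vals, symptom, "pearson")
        excl_rows.append((net, ",".join(map(str, excluded)), res.estimate, res.p, res.n))
    exclusion_assoc = pd.DataFrame(
        excl_rows, columns=["unit", "excluded", "estimate", "p", "n"]
    )

    pair_rows = []
    anchor = focus[0] if focus else None
    for other in focus[1:]:
        vals = np.array(
            [between_network_fc(fc, partition, anchor, other) for fc in fcs]
        )
        res = correlation_test(vals, symptom, "pearson")
        pair_rows.append((f"{anchor}|{other}", res.estimate, res.p, res.n))
    pair_assoc = pd.DataFrame(pair_rows, columns=["pair", "estimate", "p", "n"])

    factor_names = list(config.factor_map)
    partial_rows = []
    for net in focus:
        bgc_vals = net_df.loc[net].to_numpy()
        for name in factor_names:
            others = np.column_stack(
                [factor_raw[o] for o in factor_names if o != name]
            )
            res = partial_rank_correlation(bgc_vals, factor_raw[name], others)
            partial_rows.append((net, name, res.estimate, res.p, res.df, res.n))
    factor_partials = pd.DataFrame(
        partial_rows, columns=["unit", "factor", "estimate", "p", "df", "n"]
    )

    cmp_rows = []
    for net in focus:
        r_bgc = float(
            network_assoc.loc[network_assoc["unit"] == net, "estimate"].iloc[0]
        )
        r_within = float(
            within_assoc.loc[within_assoc["unit"] == net, "estimate"].iloc[0]
        )
        cmp_res = compare_correlations(r_bgc, n, r_within, n)
        cmp_rows.append((net, r_bgc, r_within, cmp_res.z, cmp_res.p))
    comparisons = pd.DataFrame(
        cmp_rows, columns=["unit", "r_bgc", "r_within", "z", "p"]
    )

    alt_assoc = None
    if alt_partition is not None:
        alt_df = pd.DataFrame(alt_net_bgc, index=kept_ids).T
        alt_assoc = association_table(alt_df, symptom, "pearson", fdr=True)

    scrub_summary = pd.DataFrame(
        scrub_rows,
        columns=[
            "subject_id",
            "n_frames",
            "n_censored",
            "n_retained",
            "mean_fd_raw",
            "dropped",
        ],
    )

    cfg_dict = config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    provenance = {
        "netbgc_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "n_subjects_analyzed": n,
        "n_subjects_dropped": int(scrub_summary["dropped"].sum()),
        "focus_networks": list(focus),
    }

    return AnalysisReport(
        network_associations=network_assoc,
        region_associations=region_assoc,
        spearman_associations=spearman_assoc,
        residualized_associations=resid_assoc,
        within_network_associations=within_assoc,
        exclusion_associations=exclusion_assoc,
        between_network_fc_associations=pair_assoc,
        factor_partial_correlations=factor_partials,
        correlation_comparisons=comparisons,
        normality_diagnostics=normality,
        scrub_summary=scrub_summary,
        alt_network_associations=alt_assoc,
        focus_networks=focus,
        n_subjects=n,
        provenance=provenance,
    )


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Serialize every table as TSV plus a YAML summary, deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables().items():
        table.to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(report.provenance, fh, sort_keys=True)


def render_summary(tables_dir: str | Path) -> str:
    """Human-readable digest re-rendered from stored report tables."""
    tables_dir = Path(tables_dir)
    lines = []
    net_path = tables_dir / "network_associations.tsv"
    if net_path.exists():
        net = pd.read_csv(net_path, sep="\t")
        lines.append("Network BGC-symptom associations (Pearson, BH-FDR):")
        for _, row in net.sort_values("estimate").iterrows():
            lines.append(
                f"  {row['unit']:<22s} r={row['estimate']:+.3f} "
                f"p={row['p']:.3f} p_fdr={row['p_fdr']:.3f}"
            )
    summary_path = tables_dir / "summary.yaml"
    if summary_path.exists():
        with open(summary_path) as fh:
            prov = yaml.safe_load(fh)
        lines.append(
            f"n={prov.get('n_subjects_analyzed')} subjects analyzed, "
            f"{prov.get('n_subjects_dropped')} dropped; "
            f"focus networks: {', '.join(prov.get('focus_networks', []))}"
        )
    return "\n".join(lines)
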