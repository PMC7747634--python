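"""Body-size scaling of community-assembly metrics, and pipeline orchestration.

This is the synthesis layer: it runs every per-group analysis (alpha
diversity, distance-decay, β-null deviation, Sloan dispersal rate, OMI,
variation partitioning) over the dominant groups of a study, joins the
results with the groups' body sizes, and regresses each assembly metric
on log10 body size.  A batch harness pools group-level NDVs over many
studies, stratified by ecosystem, for meta-analysis-style scaling fits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import beta_null, ddr, metrics, neutral, omi, varpart
from .data_model import (
    CountTable,
    filter_dominant_groups,
    rarefy,
    read_body_sizes,
    read_count_table,
    read_metadata,
    read_taxon_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupMetrics",
    "RegressionResult",
    "PipelineConfig",
    "PipelineResult",
    "regress_on_size",
    "compare_groups",
    "run_pipeline",
    "meta_batch",
]


@dataclass
class GroupMetrics:
    group: str
    size_um: float | None = None
    mean_ndv: float | None = None
    mean_abs_ndv: float | None = None
    m: float | None = None
    neutral_r2: float | None = None
    mean_omi: float | None = None
    ddr_slope: float | None = None
    ddr_r2: float | None = None
    d_h: float | None = None
    s0: float | None = None
    chao1_mean: float | None = None
    richness_mean: float | None = None
    pure_env: float | None = None
    pure_spatial: float | None = None
    kingdom: str | None = None
    ecosystem: str | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def metrics_frame(rows: Sequence[GroupMetrics]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("group")


def regress_on_size(
    metrics_table: pd.DataFrame,
    response: str,
    scope: str | None = None,
) -> RegressionResult:
    """OLS of a metric on log10 body size across groups.

    ``scope`` restricts to one kingdom (matching the ``kingdom`` column)
    when given.  Needs at least 3 groups with a finite response.
    """
    df = metrics_table
    if scope is not None and scope != "all":
        if "kingdom" not in df.columns:
            raise ValueError("no kingdom column for within-kingdom scope")
        df = df[df["kingdom"] == scope]
    df = df.dropna(subset=[response, "size_um"])
    df = df[np.isfinite(df[response]) & np.isfinite(df["size_um"])]
    if len(df) < 3:
        raise ValueError(
            f"need >= 3 groups with finite {response!r} in scope {scope or 'all'!r}, "
            f"have {len(df)}"
        )
    res = stats.linregress(np.log10(df["size_um"].to_numpy()), df[response].to_numpy())
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(df),
    )


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame            # pairwise Tukey HSD p-values
    letters: dict[str, str]        # compact letter display
    means: dict[str, float]


def _letter_display(names: list[str], means: dict[str, float], sig: set[tuple[str, str]]) -> dict[str, str]:
    # greedy compact letters: walk groups by descending mean, reuse a letter
    # whenever the group is not significantly different from every current holder
    ordered = sorted(names, key=lambda g: -means[g])
    letters: dict[str, str] = {g: "" for g in names}
    holders: list[list[str]] = []
    for g in ordered:
        placed = False
        for members in holders:
            if all((min(g, h), max(g, h)) not in sig for h in members):
                members.append(g)
                placed = True
        if not placed:
            holders.append([g])
    for k, members in enumerate(holders):
        ch = chr(ord("a") + k)
        for g in members:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in names}


def compare_groups(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA across categories with Tukey HSD post-hoc pairwise
    comparisons and a compact letter display (groups sharing a letter do
    not differ at ``alpha``)."""
    names = list(values)
    if len(names) < 2:
        raise ValueError("need at least 2 categories")
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    small = [g for g, a in zip(names, arrays) if len(a) < 2]
    if small:
        raise ValueError(f"categories with fewer than 2 values: {small}")
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    sig: set[tuple[str, str]] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pv = float(hsd.pvalue[i, j])
            rows.append({"group1": names[i], "group2": names[j], "p": pv})
            if pv < alpha:
                sig.add((min(names[i], names[j]), max(names[i], names[j])))
    means = {g: float(a.mean()) for g, a in zip(names, arrays)}
    return GroupComparison(
        f_statistic=float(f),
        p_value=float(p),
        tukey=pd.DataFrame(rows),
        letters=_letter_display(names, means, sig),
        means=means,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    depth: int | None = None        # rarefaction depth; None -> min row sum
    min_rel_abund: float = 0.01
    min_presence: float = 0.80
    ndv_reps: int = 999
    n_perm: int = 199               # forward selection / varpart permutations
    alpha: float = 0.05
    n_boot: int = 0                 # binomial-comparison bootstraps; 0 skips
    seed: int = 0
    run_varpart: bool = True


@dataclass
class PipelineResult:
    group_metrics: pd.DataFrame
    regressions: pd.DataFrame
    varpart: dict[str, varpart.VarPartResult]
    errors: dict[str, str]
    manifest: dict


def _sloan_for_group(sub: CountTable) -> neutral.NeutralFit:
    # group sub-tables of an evenly rarefied whole table have unequal row
    # sums; fit with N = the mean number of group reads per sample
    nonempty = sub.drop_empty_samples()
    n_ind = int(round(nonempty.row_sums.mean()))
    return neutral.fit_sloan(nonempty, n_individuals=max(n_ind, 1))


def run_pipeline(
    study_dir: str | Path, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full per-group analysis on a study directory.

    Expects ``counts.tsv``, ``metadata.csv``, ``taxa.tsv`` and (for the
    scaling stage) ``sizes.csv``.  Stage failures are recorded per group
    and the pipeline continues where possible.
    """
    cfg = config or PipelineConfig()
    d = Path(study_dir)
    table = read_count_table(d / "counts.tsv")
    samples = read_metadata(d / "metadata.csv")
    taxa = read_taxon_map(d / "taxa.tsv")
    sizes_path = d / "sizes.csv"
    sizes = (
        {r.group: r.size_um for r in read_body_sizes(sizes_path)}
        if sizes_path.exists()
        else None
    )
    sample_order = [s.sample_id for s in samples]
    if set(sample_order) != set(table.sample_ids):
        raise ValueError("metadata and count table sample ids do not match")
    table = table.select_samples(sample_order)

    depth = cfg.depth if cfg.depth is not None else int(table.row_sums.min())
    if len(set(table.row_sums.tolist())) != 1 or cfg.depth is not None:
        table = rarefy(table, depth, seed=cfg.seed)

    groups = filter_dominant_groups(table, taxa, cfg.min_rel_abund, cfg.min_presence)
    geo = metrics.geographic_distance(samples)
    env_vars = list(samples[0].env)
    env_std = omi.standardize_environment(samples, env_vars) if env_vars else None
    mem = varpart.build_mem(geo) if cfg.run_varpart and len(samples) >= 4 else None

    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    ndv_results = beta_null.group_ndv(
        table, taxa, groups, n_reps=cfg.ndv_reps, seed=int(seeds[0].generate_state(1)[0] % 2**31)
    )
    ndv_by_group = dict(ndv_results)

    rows: list[GroupMetrics] = []
    errors: dict[str, str] = {}
    vp_results: dict[str, varpart.VarPartResult] = {}
    vp_seeds = seeds[1].spawn(len(groups))
    for (group, sub), vseed in zip(groups, vp_seeds):
        gm = GroupMetrics(group=group, size_um=sizes.get(group) if sizes else None)
        nonempty = sub.drop_empty_samples()
        alpha_div = metrics.alpha_diversity(nonempty)
        gm.richness_mean = float(np.mean([a.richness for a in alpha_div]))
        gm.chao1_mean = float(np.mean([a.chao1 for a in alpha_div]))
        if group in ndv_by_group:
            res = ndv_by_group[group]
            gm.mean_ndv = res.mean_ndv
            gm.mean_abs_ndv = res.mean_abs_ndv
        try:
            bc = metrics.bray_curtis(nonempty)
            sub_geo_ids = nonempty.sample_ids
            idx = [geo.ids.index(s) for s in sub_geo_ids]
            sub_geo = metrics.DistanceMatrix(
                sub_geo_ids, geo.values[np.ix_(idx, idx)], "km"
            )
            fit = ddr.fit_ddr(bc, sub_geo)
            gm.ddr_slope, gm.ddr_r2 = fit.b, fit.r_squared
            gm.d_h, gm.s0 = fit.d_h, fit.s0
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            errors[f"{group}/ddr"] = str(exc)
        try:
            sloan = _sloan_for_group(sub)
            gm.m, gm.neutral_r2 = sloan.m, sloan.r_squared
        except Exception as exc:  # noqa: BLE001
            errors[f"{group}/neutral"] = str(exc)
        if env_std is not None:
            try:
                records = omi.omi_per_otu(sub, env_std)
                gm.mean_omi = float(np.mean([r.omi for r in records]))
            except Exception as exc:  # noqa: BLE001
                errors[f"{group}/omi"] = str(exc)
        if cfg.run_varpart and mem is not None and env_std is not None:
            try:
                vseed_int = int(vseed.generate_state(1)[0] % 2**31)
                sel_env = varpart.forward_select(
                    sub, env_std, cfg.alpha, cfg.n_perm, seed=vseed_int
                )
                sel_mem = varpart.forward_select(
                    sub, mem, cfg.alpha, cfg.n_perm, seed=vseed_int + 1
                )
                if sel_env or sel_mem:
                    vp = varpart.variation_partition(
                        sub,
                        env_std[sel_env] if sel_env else None,
                        mem[sel_mem] if sel_mem else None,
                        n_perm=cfg.n_perm,
                        seed=vseed_int + 2,
                    )
                    vp_results[group] = vp
                    gm.pure_env, gm.pure_spatial = vp.pure_env, vp.pure_spatial
            except Exception as exc:  # noqa: BLE001
                errors[f"{group}/varpart"] = str(exc)
        rows.append(gm)

    gm_frame = metrics_frame(rows)
    reg_rows = []
    if sizes is None:
        errors["scaling"] = "sizes.csv missing: body-size regressions skipped"
    else:
        for response in ("mean_ndv", "m", "mean_omi", "ddr_slope", "d_h", "s0",
                         "chao1_mean", "richness_mean"):
            try:
                r = regress_on_size(gm_frame, response)
                reg_rows.append({"response": response, **dataclasses.asdict(r)})
            except ValueError as exc:
                errors[f"scaling/{response}"] = str(exc)
    manifest = {
        "study_dir": str(d),
        "depth": depth,
        "config": dataclasses.asdict(cfg),
        "groups": [g for g, _ in groups],
        "n_samples": table.n_samples,
    }
    return PipelineResult(
        group_metrics=gm_frame,
        regressions=pd.DataFrame(reg_rows),
        varpart=vp_results,
        errors=errors,
        manifest=manifest,
    )


def write_pipeline_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.group_metrics.to_csv(out / "group_metrics.csv")
    result.regressions.to_csv(out / "scaling_regressions.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    vp = {g: dataclasses.asdict(v) for g, v in result.varpart.items()}
    (out / "varpart.json").write_text(json.dumps(vp, indent=2, default=str))
    if result.errors:
        (out / "errors.json").write_text(json.dumps(result.errors, indent=2))


def meta_batch(
    studies: Sequence[Mapping[str, object]],
    n_reps: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pooled group-level NDVs over many studies.

    Each entry needs a ``path`` (study directory) and may carry
    ``kingdom`` and ``ecosystem`` labels.  Returns one row per
    (study, group) with mean NDV and body size, ready for
    :func:`regress_on_size` within ecosystem strata.  Malformed studies
    are skipped with a logged reason.
    """
    if len(studies) < 1:
        raise ValueError("no studies given")
    rows = []
    # one seed pair derived from the master seed and shared by all studies,
    # so identical studies yield identical NDVs regardless of batch order
    state = np.random.SeedSequence(seed).generate_state(2)
    rarefy_seed, ndv_seed = int(state[0] % 2**31), int(state[1] % 2**31)
    for entry in studies:
        path = Path(str(entry["path"]))
        try:
            table = read_count_table(path / "counts.tsv")
            taxa = read_taxon_map(path / "taxa.tsv")
            sizes_path = path / "sizes.csv"
            sizes = (
                {r.group: r.size_um for r in read_body_sizes(sizes_path)}
                if sizes_path.exists()
                else {}
            )
            if len(set(table.row_sums.tolist())) != 1:
                table = rarefy(table, int(table.row_sums.min()), seed=rarefy_seed)
            groups = filter_dominant_groups(table, taxa)
            results = beta_null.group_ndv(
                table, taxa, groups, n_reps=n_reps, seed=ndv_seed
            )
        except Exception as exc:  # noqa: BLE001 - harness skips bad studies
            logger.warning("study %s skipped: %s", path, exc)
            continue
        for group, res in results:
            rows.append(
                {
                    "study": path.name,
                    "group": group,
                    "size_um": sizes.get(group, np.nan),
                    "mean_ndv": res.mean_ndv,
                    "kingdom": entry.get("kingdom"),
                    "ecosystem": entry.get("ecosystem"),
                }
            )
    return pd.DataFrame(rows)
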