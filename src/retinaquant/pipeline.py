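"""End-to-end orchestration: simulate -> count -> qPCR -> stats -> report.

A run is driven by a single YAML config (see :class:`RunConfig`) and is
deterministic given its root seed: per-fish scene seeds and the qPCR seed are
spawned from the root via ``numpy.random.SeedSequence``, and every output CSV
is byte-identical across re-runs of the same config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counting, qpcr, stats, synthetic
from .errors import ConfigurationError
from .imaging import RegionOfInterest, write_stack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "render_report"]


@dataclass
class RunConfig:
    """Declarative description of a full synthetic experiment.

    ``groups`` entries carry (line, treatment, dpi, n_fish) plus optional
    per-group scene overrides; ``count_combos`` lists the marker combinations
    to count per fish; ``comparisons`` describes the statistical plan.
    """

    seed: int = 0
    scene_defaults: dict = field(default_factory=dict)
    groups: list[dict] = field(default_factory=list)
    segmentation: dict = field(default_factory=dict)
    count_combos: list[list[str]] = field(default_factory=lambda: [["DAPI", "PCNA"]])
    qpcr_design: dict | None = None
    qpcr_calibrator: dict = field(default_factory=lambda: {"treatment": "saline"})
    qpcr_match_dpi: bool = True
    comparisons: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    adjust: str = "holm"
    write_qc_masks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("run config needs at least one group")
        for g in self.groups:
            for key in ("line", "treatment", "dpi", "n_fish"):
                if key not in g:
                    raise ConfigurationError(f"group entry missing {key!r}: {g}")


def _full_frame_roi(height: int, width: int) -> RegionOfInterest:
    return RegionOfInterest(
        kind="polygon",
        vertices=np.array(
            [[-0.5, -0.5], [-0.5, width - 0.5], [height - 0.5, width - 0.5], [height - 0.5, -0.5]]
        ),
        label="full_frame",
    )


def _scene_for(config: RunConfig, group: dict, seed: int) -> synthetic.SceneConfig:
    fields = dict(config.scene_defaults)
    fields.update(group.get("scene", {}))
    fields["seed"] = seed
    # YAML round-trips tuples as lists; normalize the tuple-valued fields
    if "layer_bands" in fields:
        fields["layer_bands"] = [tuple(b) for b in fields["layer_bands"]]
    for key in ("nucleus_radius_um", "leukocyte_radius_um"):
        if key in fields:
            fields[key] = tuple(fields[key])
    return synthetic.SceneConfig(**fields)


def run_experiment(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline; returns paths of the emitted artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"root_seed: {config.seed}"]

    ss = np.random.SeedSequence(config.seed)
    n_scenes = sum(int(g["n_fish"]) for g in config.groups)
    children = ss.spawn(n_scenes + 1)
    qpcr_seed_seq, scene_seqs = children[0], children[1:]

    seg = counting.SegmentationParams(**config.segmentation)
    count_rows: list[dict] = []
    truth_rows: list[dict] = []
    scene_idx = 0
    for group in config.groups:
        for fish in range(int(group["n_fish"])):
            seed = int(scene_seqs[scene_idx].generate_state(1)[0])
            scene_idx += 1
            scfg = _scene_for(config, group, seed)
            stack, truth = synthetic.generate_section(scfg)
            sample_id = f"{group['line']}|{group['treatment']}|{group['dpi']}dpi|f{fish + 1}"
            roi = _full_frame_roi(*stack.shape_yx)
            for combo in config.count_combos:
                combo = list(combo)
                missing = [c for c in combo if not stack.has_channel(c)]
                if missing:
                    logger.warning("%s: skipping combo %s (missing %s)", sample_id, combo, missing)
                    continue
                if len(combo) == 2:
                    rec = counting.count_coloc(
                        stack, combo[0], combo[1], roi, seg,
                        sample_id=sample_id, line=group["line"],
                        treatment=group["treatment"], dpi=int(group["dpi"]),
                    )
                elif len(combo) == 1:
                    rec = counting.count_single_marker(
                        stack, combo[0], roi, seg,
                        sample_id=sample_id, line=group["line"],
                        treatment=group["treatment"], dpi=int(group["dpi"]),
                    )
                else:
                    raise ConfigurationError(f"count combos must have 1 or 2 channels: {combo}")
                count_rows.append(rec.as_dict())
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "marker_combo": rec.marker_combo,
                        "true_count": truth.count(tuple(combo)),
                    }
                )
            if config.write_qc_masks:
                qc_dir = outdir / "qc"
                qc_dir.mkdir(exist_ok=True)
                write_stack(stack, qc_dir / f"{sample_id.replace('|', '_')}.ome.tif")
            log_lines.append(f"scene {sample_id}: seed={seed}")

    artifacts: dict[str, Path] = {}
    counts_df = pd.DataFrame(count_rows)
    counts_path = outdir / "counts.csv"
    counts_df.to_csv(counts_path, index=False, float_format="%.10g")
    artifacts["counts"] = counts_path
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth_counts.csv", index=False)
    artifacts["ground_truth_counts"] = outdir / "ground_truth_counts.csv"

    folds_df = None
    if config.qpcr_design:
        design_fields = dict(config.qpcr_design)
        design_fields.setdefault(
            "groups",
            [(g["line"], g["treatment"], int(g["dpi"])) for g in config.groups],
        )
        design_fields["groups"] = [tuple(g) for g in design_fields["groups"]]
        if "programmed_log2_fold" in design_fields and isinstance(
            design_fields["programmed_log2_fold"], list
        ):
            # YAML-friendly list form: [{gene, line, treatment, dpi, log2_fold}]
            design_fields["programmed_log2_fold"] = {
                (e["gene"], (e["line"], e["treatment"], int(e["dpi"]))): float(e["log2_fold"])
                for e in design_fields["programmed_log2_fold"]
            }
        design_fields["seed"] = int(qpcr_seed_seq.generate_state(1)[0])
        design = synthetic.QpcrDesign(**design_fields)
        table = synthetic.generate_qpcr(design)
        ct_path = outdir / "ct.csv"
        table.to_csv(ct_path, index=False, float_format="%.10g")
        artifacts["ct"] = ct_path

        fold_frames = []
        dpis = sorted({int(g["dpi"]) for g in config.groups}) if config.qpcr_match_dpi else [None]
        for gene in design.genes:
            if gene == design.reference_gene:
                continue
            for dpi in dpis:
                calibrator = dict(config.qpcr_calibrator)
                sub = table
                if dpi is not None:
                    calibrator["dpi"] = dpi
                    sub = table[table["dpi"] == dpi]
                if sub.empty:
                    continue
                result = qpcr.delta_delta_ct(sub, gene, design.reference_gene, calibrator)
                frame = result.per_sample.copy()
                frame.insert(0, "gene", gene)
                fold_frames.append(frame)
        folds_df = pd.concat(fold_frames, ignore_index=True)
        folds_path = outdir / "folds.csv"
        folds_df.to_csv(folds_path, index=False, float_format="%.10g")
        artifacts["folds"] = folds_path

    stats_rows = []
    for comp in config.comparisons:
        stats_rows.append(_run_comparison(comp, counts_df, folds_df))
    if stats_rows:
        stats_df = pd.DataFrame(stats_rows)
        if config.adjust != "none" and len(stats_df) > 0:
            p = stats_df["p_value"].to_numpy()
            if config.adjust == "holm":
                stats_df["p_adjusted"] = stats.holm_adjust(p)
            elif config.adjust == "bonferroni":
                stats_df["p_adjusted"] = np.minimum(1.0, p * len(p))
            else:
                raise ConfigurationError(f"unknown adjustment {config.adjust!r}")
        else:
            stats_df["p_adjusted"] = stats_df["p_value"]
        stats_df["significant"] = stats_df["p_adjusted"] < config.alpha
        stats_path = outdir / "stats.csv"
        stats_df.to_csv(stats_path, index=False, float_format="%.10g")
        artifacts["stats"] = stats_path

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = outdir / "run.log"
    return artifacts


def _select(df: pd.DataFrame, selector: dict) -> pd.DataFrame:
    mask = pd.Series(True, index=df.index)
    for key, value in selector.items():
        if key not in df.columns:
            raise ConfigurationError(f"selector key {key!r} not a column")
        if key == "dpi":
            mask &= df[key].astype(int) == int(value)
        else:
            mask &= df[key].astype(str) == str(value)
    return df[mask]


def _run_comparison(comp: dict, counts_df: pd.DataFrame, folds_df: pd.DataFrame | None) -> dict:
    source = comp.get("source", "counts")
    if source == "counts":
        df = counts_df
        value_col = comp.get("value", "density")
        df = df[df["marker_combo"] == comp["marker"]] if "marker" in comp else df
        name = comp.get("name", f"{comp.get('marker', 'counts')}")
    elif source == "qpcr":
        if folds_df is None:
            raise ConfigurationError("comparison references qPCR but no design configured")
        df = folds_df[folds_df["gene"] == comp["gene"]]
        value_col = comp.get("value", "fold_change")
        name = comp.get("name", comp["gene"])
    else:
        raise ConfigurationError(f"unknown comparison source {source!r}")

    test = comp.get("test", "welch")
    if test == "welch":
        a = _select(df, comp["a"])[value_col].to_numpy()
        b = _select(df, comp["b"])[value_col].to_numpy()
        res = stats.welch_test(a, b)
        return {
            "comparison": name,
            "test": "welch",
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
        }
    if test in ("kw", "kw-conover"):
        by = comp.get("by", "line")
        base = _select(df, comp.get("where", {}))
        groups = {
            str(k): sub[value_col].to_numpy() for k, sub in base.groupby(by, sort=True)
        }
        res = stats.kruskal_wallis(groups)
        row = {
            "comparison": name,
            "test": test,
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
        }
        if test == "kw-conover":
            post = stats.conover_posthoc(groups, adjust="none")
            pairs = post.pairwise_p
            labels = list(pairs.index)
            row["min_pairwise_p"] = float(
                min(
                    pairs.iloc[i, j]
                    for i in range(len(labels))
                    for j in range(i + 1, len(labels))
                )
            )
        return row
    raise ConfigurationError(f"unknown test {test!r}")


def render_report(outdir: str | Path) -> str:
    """Plain-text summary of a completed run directory."""
    outdir = Path(outdir)
    lines = [f"run report: {outdir}", "=" * 40]
    stats_path = outdir / "stats.csv"
    if stats_path.exists():
        df = pd.read_csv(stats_path)
        lines.append(f"{'comparison':30s} {'test':10s} {'p_adj':>10s}  sig")
        for _, r in df.iterrows():
            lines.append(
                f"{str(r['comparison'])[:30]:30s} {r['test']:10s} "
                f"{r['p_adjusted']:10.4g}  {'*' if r['significant'] else ''}"
            )
    else:
        lines.append("no stats.csv found")
    counts_path = outdir / "counts.csv"
    if counts_path.exists():
        df = pd.read_csv(counts_path)
        lines.append("")
        lines.append("mean density by group and marker:")
        summary = (
            df.groupby(["marker_combo", "line", "treatment", "dpi"])["density"]
            .mean()
            .reset_index()
        )
        for _, r in summary.iterrows():
            lines.append(
                f"  {r['marker_combo']:16s} {r['line']:14s} {r['treatment']:8s} "
                f"{int(r['dpi']):3d}dpi  {r['density']:.4g}"
            )
    return "\n".join(lines)
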