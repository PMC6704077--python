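"""End-to-end orchestration: synthesize a head, simulate every montage,
run the three-principle selection, and write machine-readable artifacts.

Every run is fully determined by its :class:`RunConfig`; all randomness is
seeded and the config hash is stamped into every JSON report, so rerunning
the same config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .io import (
    AtlasLabelTable,
    FieldVector,
    MscopeError,
    NodeCloud,
    logger,
    write_field_vector,
    write_label_table,
    write_node_cloud,
)
from .lobes import anova_across_lobes, lobe_statistics
from .selection import SelectionReport, SelectionTargets, select
from .sensitivity import displacement_sensitivity, intensity_sensitivity
from .synth import (
    DEFAULT_HEAD_RADIUS,
    SimulationParams,
    build_head_model,
    enumerate_paper_montages,
    layout_electrodes,
    parse_montage_name,
    simulate_field,
)


@dataclass
class RunConfig:
    """Complete description of one experiment run."""

    n_nodes: int = 35057
    head_seed: int = 1
    head_radius: float = DEFAULT_HEAD_RADIUS
    sim: SimulationParams = field(default_factory=SimulationParams)
    montage_names: list[str] | None = None   # None -> the 10 study montages
    sizes: list[tuple[float, float]] = field(
        default_factory=lambda: [(5.0, 5.0), (3.0, 3.0), (5.0, 7.0)])
    fraction: float = 0.5
    targets: SelectionTargets = field(default_factory=SelectionTargets)
    scope: str = "survivors"
    run_sensitivity: bool = True
    sensitivity_seeds: list[int] = field(
        default_factory=lambda: list(range(1, 21)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets"] = {
            "dorsal_target_lobe": list(self.targets.dorsal_target_lobe),
            "dorsal_target_gyri": sorted(self.targets.dorsal_target_gyri),
            "ventral_target_lobe": list(self.targets.ventral_target_lobe),
            "ventral_target_gyri": sorted(self.targets.ventral_target_gyri),
            "top_k_for_verification": self.targets.top_k_for_verification,
        }
        d["sizes"] = [list(s) for s in self.sizes]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimulationParams(**kwargs["sim"])
        if "targets" in kwargs:
            t = kwargs["targets"]
            kwargs["targets"] = SelectionTargets(
                dorsal_target_lobe=tuple(t.get("dorsal_target_lobe",
                                                ("left", "parietal"))),
                dorsal_target_gyri=frozenset(
                    t.get("dorsal_target_gyri", {"Supramarginal Gyrus"})),
                ventral_target_lobe=tuple(t.get("ventral_target_lobe",
                                                 ("left", "temporal"))),
                ventral_target_gyri=frozenset(
                    t.get("ventral_target_gyri",
                          {"Middle Temporal Gyrus",
                           "Inferior Temporal Gyrus"})),
                top_k_for_verification=t.get("top_k_for_verification", 5))
        if "sizes" in kwargs:
            kwargs["sizes"] = [tuple(s) for s in kwargs["sizes"]]
        return cls(**kwargs)


def simulate_montages(config: RunConfig, cloud: NodeCloud,
                      size: tuple[float, float]
                      ) -> tuple[dict[str, FieldVector],
                                 dict[str, FieldVector]]:
    """Fields for every study montage at one pad size, split by pathway.

    Per-montage noise seeds derive deterministically from the config's
    simulation seed and the montage's position in the list.
    """
    layout = layout_electrodes(config.head_radius)
    if config.montage_names is None:
        specs = enumerate_paper_montages(size[0], size[1])
    else:
        specs = [replace(parse_montage_name(n), size_l=size[0],
                         size_b=size[1]) for n in config.montage_names]
    dorsal, ventral = {}, {}
    for i, spec in enumerate(specs):
        fv = simulate_field(spec, cloud, layout, config.sim,
                            seed=config.sim.seed + i)
        (dorsal if spec.anode_label == "CP5" else ventral)[spec.name] = fv
    return dorsal, ventral


def _dump(obj: dict, path: Path, stamp: dict) -> None:
    with open(path, "w") as fh:
        json.dump({**stamp, **obj}, fh, indent=1, default=str)


def run_paper_experiment(config: RunConfig, out_dir,
                         force: bool = False) -> SelectionReport:
    """Full study run: head synthesis, 10 montages x the configured sizes,
    lobe statistics, selection, and sensitivity on the winners.

    Writes TSV artifacts for all per-node data and JSON for every report,
    each stamped with the config hash and seeds.  Refuses to write into a
    non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise MscopeError(f"output directory {out} is not empty "
                          "(pass force=True / --force to overwrite)")
    (out / "head").mkdir(parents=True, exist_ok=True)
    (out / "fields").mkdir(exist_ok=True)
    (out / "lobes").mkdir(exist_ok=True)
    stamp = {"config_hash": config.config_hash(),
             "head_seed": config.head_seed, "sim_seed": config.sim.seed}

    logging.getLogger("mscope").info("run %s: building %d-node head model",
                                     config.config_hash(), config.n_nodes)
    cloud, labels = build_head_model(config.n_nodes, config.head_seed,
                                     head_radius=config.head_radius)
    write_node_cloud(cloud, out / "head" / "nodes.tsv")
    write_label_table(labels, out / "head" / "labels.tsv")

    primary_size = config.sizes[0]
    fields_by_size: dict[tuple[float, float],
                         tuple[dict, dict]] = {}
    for size in config.sizes:
        dorsal, ventral = simulate_montages(config, cloud, size)
        fields_by_size[size] = (dorsal, ventral)
        for name, fv in {**dorsal, **ventral}.items():
            write_field_vector(fv, out / "fields" / f"{name}.tsv")
            st = lobe_statistics(fv.restrict(labels.node_id), labels)
            an = anova_across_lobes(fv.restrict(labels.node_id), labels)
            _dump({"lobe_stats": st.to_dict(), "anova": an.to_dict()},
                  out / "lobes" / f"{name}.json", stamp)

    dorsal, ventral = fields_by_size[primary_size]
    labeled = {n: f.restrict(labels.node_id) for n, f in dorsal.items()}
    labeled_v = {n: f.restrict(labels.node_id) for n, f in ventral.items()}
    report = select(labeled, labeled_v, labels, config.targets,
                    fraction=config.fraction, scope=config.scope)
    _dump(report.to_dict(), out / "report.json", stamp)

    if config.run_sensitivity and report.final_pair:
        layout = layout_electrodes(config.head_radius)
        sens = {}
        for name in report.final_pair:
            spec = parse_montage_name(name)
            disp = displacement_sensitivity(spec, cloud, labels, layout,
                                            config.sim, seed=config.sim.seed)
            inten = intensity_sensitivity(
                spec, cloud, labels, layout, config.sim,
                seeds=config.sensitivity_seeds
                if config.sim.noise_sd > 0 else None)
            sens[name] = {"displacement": disp.to_dict(),
                          "intensity": inten.to_dict()}
        _dump(sens, out / "sensitivity.json", stamp)

    logger.info("run %s complete; final pair: %s", config.config_hash(),
                report.final_pair)
    return report
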