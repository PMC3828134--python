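"""Run configuration, report serialization and the end-to-end pipeline.

A run is configured by a flat ``key = value`` text file (namespaced keys,
'#' comments); command-line flags override file values.  Unknown keys are
rejected.  Every numeric threshold that influences a decision is echoed in
the report header so a report is auditable on its own.

The pipeline mirrors the function-prediction workflow: conservation ->
frame quenching -> ensemble search -> binding-site annotation -> complex
model, with optional trajectory analyses.  Stages are individually
skippable; a stage whose inputs are missing fails fast with a dependency
error.  With fixed seeds the pipeline is deterministic down to the bytes
of its reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate as annotate_mod
from . import conservation as conservation_mod
from .core_model import Structure, read_structure, read_trajectory
from .ensemble_search import (
    SearchReport,
    default_schedule,
    ensemble_search,
    parse_schedule,
    quench_frames,
)
from .errors import ConfigError, StageDependencyError
from .model_builder import build_complex, write_complex
from .sitegraph import CompareParams, Hit

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, str] = {
    "seed": "0",
    "out.dir": "bsfp_report",
    "query.pdb": "",
    "query.chain": "",
    "homologs": "",
    "traj.pdb": "",
    "traj.dt_ps": "1.0",
    "schedule": "0:100:5,100:1000:100",
    "db.dir": "",
    "region": "",
    "compare.d_max": "15.0",
    "compare.epsilon": "2.0",
    "compare.extend_cutoff": "3.0",
    "compare.min_clique": "3",
    "conserve.min_degree": "8",
    "conserve.patch_cutoff": "8.0",
    "search.z_min": "0.5",
    "annotate.cutoff": "3.0",
    "annotate.min_overlap": "0.5",
    "annotate.min_identity": "0.30",
    "model.clash_cutoff": "2.5",
    "model.ligand_chain": "X",
    "stage.conserve": "true",
    "stage.quench": "true",
    "stage.search": "true",
    "stage.annotate": "true",
    "stage.model": "true",
}


@dataclass
class RunConfig:
    values: dict[str, str] = field(default_factory=lambda: dict(DEFAULTS))
    provenance: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path,
                  overrides: dict[str, str] | None = None) -> "RunConfig":
        cfg = cls()
        cfg.provenance.append(f"config-file {path}")
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"bad config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            cfg.set(key, value)
        for key, value in (overrides or {}).items():
            cfg.set(key, value)
            cfg.provenance.append(f"override {key}={value}")
        return cfg

    def set(self, key: str, value: str) -> None:
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key {key!r}")
        self.values[key] = value

    def get(self, key: str) -> str:
        return self.values[key]

    def get_float(self, key: str) -> float:
        return float(self.values[key])

    def get_int(self, key: str) -> int:
        return int(self.values[key])

    def get_bool(self, key: str) -> bool:
        return self.values[key].strip().lower() in ("1", "true", "yes", "on")

    def compare_params(self) -> CompareParams:
        return CompareParams(self.get_float("compare.d_max"),
                             self.get_float("compare.epsilon"),
                             self.get_float("compare.extend_cutoff"),
                             self.get_int("compare.min_clique"))


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def parse_region(text: str) -> set[tuple[str, int]]:
    """Parse ``"A:7,A:42-45"`` into (chain, number) pairs."""
    out: set[tuple[str, int]] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        chain, _, numbers = part.partition(":")
        if not numbers:
            raise ConfigError(f"bad region element {part!r} (want chain:number)")
        if "-" in numbers[1:]:  # range; [1:] so a leading minus sign survives
            head, tail = numbers[1:].split("-", 1)
            lo, hi = int(numbers[0] + head), int(tail)
            out.update((chain, n) for n in range(lo, hi + 1))
        else:
            out.add((chain, int(numbers)))
    return out


def _ref_to_list(ref) -> list:
    return list(ref)


def hits_to_json(hits: list[Hit]) -> str:
    payload = [
        {
            "target_id": h.target_id,
            "score": h.score,
            "z_score": round(h.z_score, 10),
            "rmsd": round(h.rmsd, 10),
            "frame_index": h.frame_index,
            "rotation": [[round(x, 10) for x in row] for row in h.rotation.tolist()],
            "translation": [round(x, 10) for x in h.translation.tolist()],
            "correspondence": [[_ref_to_list(q), _ref_to_list(t)]
                               for q, t in h.correspondence],
        }
        for h in hits
    ]
    return json.dumps(payload, indent=1, sort_keys=True)


def hits_from_json(text: str) -> list[Hit]:
    hits = []
    for item in json.loads(text):
        hits.append(Hit(
            item["target_id"],
            [(tuple(q), tuple(t)) for q, t in item["correspondence"]],
            np.array(item["rotation"]), np.array(item["translation"]),
            item["rmsd"], item["score"], item["z_score"], item["frame_index"]))
    return hits


def hits_tsv(hits: list[Hit]) -> str:
    lines = ["target_id\tscore\tz_score\trmsd\tframe\tcorrespondence"]
    for h in hits:
        pairs = ",".join(
            f"{q[0]}:{q[1]}{q[2]}~{t[0]}:{t[1]}{t[2]}" for q, t in h.correspondence)
        lines.append(f"{h.target_id}\t{h.score:g}\t{h.z_score:.4f}\t"
                     f"{h.rmsd:.4f}\t{h.frame_index}\t{pairs}")
    return "\n".join(lines) + "\n"


def report_header(config: RunConfig) -> str:
    lines = ["# bsfp report"]
    for key in sorted(config.values):
        lines.append(f"# {key} = {config.values[key]}")
    for item in config.provenance:
        lines.append(f"# provenance: {item}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    out_dir: Path
    patches: list[set] | None = None
    region: set | None = None
    frames: list | None = None
    report: SearchReport | None = None
    annotated: list | None = None
    model: object | None = None


def _load_db(db_dir: str) -> dict[str, Structure]:
    paths = sorted(Path(db_dir).glob("*.pdb"))
    db: dict[str, Structure] = {}
    for p in paths:
        s = read_structure(p)
        if isinstance(s, Structure):
            db[s.id] = s
    return db


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.get("out.dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    header = report_header(config)
    result = PipelineResult(out_dir)
    params = config.compare_params()
    summary: dict[str, object] = {}

    query: Structure | None = None
    if config.get("query.pdb"):
        query = read_structure(config.get("query.pdb"),
                               chain=config.get("query.chain") or None)

    # --- conservation ------------------------------------------------------
    region = parse_region(config.get("region")) if config.get("region") else None
    if config.get_bool("stage.conserve"):
        if query is None:
            raise StageDependencyError("conserve stage requires query.pdb")
        homolog_paths = [p for p in config.get("homologs").split(",") if p.strip()]
        if not homolog_paths:
            raise StageDependencyError("conserve stage requires homologs")
        homologs = [read_structure(p.strip()) for p in homolog_paths]
        profile = conservation_mod.conservation_profile(query, homologs, params)
        patches = conservation_mod.predict_binding_site(
            profile, config.get_int("conserve.min_degree"),
            config.get_float("conserve.patch_cutoff"))
        result.patches = patches
        lines = [header, "chain\tresnum\ticode\tdegree"]
        for key in sorted(profile.degrees):
            lines.append(f"{key[0]}\t{key[1]}\t{key[2]}\t{profile.degrees[key]}")
        for i, patch in enumerate(patches):
            members = ",".join(f"{c}:{n}{i_}" for c, n, i_ in sorted(patch))
            lines.append(f"# patch {i + 1} ({len(patch)} residues): {members}")
        (out_dir / "conservation.tsv").write_text("\n".join(lines) + "\n")
        summary["n_patches"] = len(patches)
        if region is None and patches:
            region = {(c, n) for c, n, _ in patches[0]}
    if region is not None:
        result.region = region

    # --- frame quenching ---------------------------------------------------
    frames = None
    if config.get_bool("stage.quench"):
        if not config.get("traj.pdb"):
            raise StageDependencyError("quench stage requires traj.pdb")
        traj = read_trajectory(config.get("traj.pdb"),
                               dt_ps=config.get_float("traj.dt_ps"))
        schedule = (parse_schedule(config.get("schedule"))
                    if config.get("schedule") else default_schedule())
        frames = quench_frames(traj, schedule)
        result.frames = frames
        summary["n_quenched_frames"] = len(frames)
    elif query is not None:
        frames = [query]

    # --- ensemble search ---------------------------------------------------
    db: dict[str, Structure] | None = None
    if config.get_bool("stage.search"):
        if frames is None:
            raise StageDependencyError("search stage requires quenched frames "
                                       "or a query structure")
        if region is None:
            raise StageDependencyError("search stage requires a region "
                                       "(conserve stage or explicit region=)")
        if not config.get("db.dir"):
            raise StageDependencyError("search stage requires db.dir")
        db = _load_db(config.get("db.dir"))
        report = ensemble_search(frames, region, list(db.values()), params,
                                 config.get_float("search.z_min"))
        result.report = report
        (out_dir / "hits.tsv").write_text(header + hits_tsv(report.hits))
        (out_dir / "hits.json").write_text(hits_to_json(report.hits) + "\n")
        summary["n_hits"] = len(report.hits)

    # --- annotation --------------------------------------------------------
    annotated = None
    if config.get_bool("stage.annotate"):
        if result.report is None:
            raise StageDependencyError("annotate stage requires search results")
        assert db is not None
        annotated = annotate_mod.filter_hits_by_sites(
            result.report.hits, db, None,
            config.get_float("annotate.min_overlap"),
            config.get_float("annotate.cutoff"), params)
        result.annotated = annotated
        lines = [header, "rank\ttarget_id\tligand_class\toverlap\tz_score"]
        for rank, a in enumerate(annotated, start=1):
            lines.append(f"{rank}\t{a.hit.target_id}\t{a.ligand_class}\t"
                         f"{a.overlap_fraction:.3f}\t{a.hit.z_score:.4f}")
        (out_dir / "annotated.tsv").write_text("\n".join(lines) + "\n")
        summary["n_annotated"] = len(annotated)

    # --- complex model -----------------------------------------------------
    if config.get_bool("stage.model"):
        if annotated is None:
            raise StageDependencyError("model stage requires annotated hits")
        if not annotated:
            summary["model"] = "no annotated hit to model from"
        else:
            if query is None:
                raise StageDependencyError("model stage requires query.pdb")
            assert db is not None and region is not None
            best = annotated[0]
            template = db[best.hit.target_id]
            site = best.matched_sites[0]
            model = build_complex(query, region, template, site.residues,
                                  site.ligand, params,
                                  config.get_float("model.clash_cutoff"))
            result.model = model
            write_complex(model, out_dir / "complex.pdb",
                          config.get("model.ligand_chain"))
            clash_lines = [header, "receptor_atom\tligand_atom_index\tdistance"]
            for (key, name), j, d in model.clash_pairs:
                clash_lines.append(f"{key[0]}:{key[1]}{key[2]}:{name}\t{j}\t{d:.3f}")
            (out_dir / "clashes.tsv").write_text("\n".join(clash_lines) + "\n")
            summary["model_template"] = best.hit.target_id
            summary["model_clash_count"] = model.clash_count

    (out_dir / "summary.json").write_text(
        json.dumps({"thresholds": dict(sorted(config.values.items())),
                    "summary": summary}, indent=1, sort_keys=True) + "\n")
    return result
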