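"""End-to-end workflow: omic states -> IPLs -> null filter -> groups.

The eight stages run in a fixed order:

1. ternary CNA/RNA states from the omic matrices;
2. factor-graph inference of IPLs on the real samples;
3. within-patient permutations of the paired states;
4. IPL inference on the permuted samples and the MAD null filter;
5. largest-connected-component retention and pathway states;
6. gene-set overrepresentation profiles and patient grouping;
7. group-consensus submodules and key proteins;
8. survival stratification by key-protein activation.

``run_pipeline`` works on in-memory frames and returns a results
bundle; ``run_pipeline_files`` wraps it with TSV/GMT I/O, writes every
artifact plus a manifest (parameters, seed, input checksums), and
persists partial outputs up to a failed stage.  Reruns with identical
inputs and parameters are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discovery import (
    Submodule,
    find_submodules,
    logrank_test,
    stratify_by_activation,
)
from .factor_graph import InferenceOptions, infer_cohort_ipls
from .ipl_filter import mad_filter_matrix, pathway_states
from .omic_states import cna_state, fit_rna_reference, rna_state
from .pathway_io import GeneSetCollection, PathwayNetwork, parse_pathway_file, read_gmt
from .perm_null import PermutationPlan, generate_permutations
from .profiles import (
    build_profile_matrix,
    cluster_patients,
    overrepresentation_cohort,
    select_display_terms,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "StageError",
    "run_pipeline",
    "run_pipeline_files",
    "split_cohort",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, parameters and the seed for one pipeline run."""

    pathway_file: str | None = None
    gmt_file: str | None = None
    cna_file: str | None = None
    rna_tumor_file: str | None = None
    rna_normal_file: str | None = None
    clinical_file: str | None = None
    out_dir: str = "pathact_out"

    k_sd: float = 2.0
    n_perm: int = 100
    k_mad: float = 3.0
    min_submodule_size: int = 5
    k_groups: int = 2
    q_threshold: float = 0.05
    frac_threshold: float = 0.9
    profile_source: str = "ipl"  # ipl | cna | rna
    profile_cap: float = 10.0
    epsilon: float = 0.1
    eta: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.profile_source not in {"ipl", "cna", "rna"}:
            raise ValueError("profile_source must be ipl, cna or rna")
        if self.k_sd <= 0 or self.k_mad <= 0:
            raise ValueError("k_sd and k_mad must be positive")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.k_groups < 1:
            raise ValueError("k_groups must be >= 1")
        for path in (
            self.pathway_file,
            self.gmt_file,
            self.cna_file,
            self.rna_tumor_file,
            self.rna_normal_file,
            self.clinical_file,
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


@dataclass
class PipelineResult:
    """Everything the eight stages produce, in memory."""

    cna_states: pd.DataFrame
    rna_states: pd.DataFrame
    ipls: pd.DataFrame
    perm_ipls: pd.DataFrame
    filtered_ipls: pd.DataFrame
    retained: dict[str, frozenset[str]]
    states: pd.DataFrame
    enrichment_adj_p: pd.DataFrame
    profile: pd.DataFrame
    groups: pd.Series
    display_terms: dict[int, list[str]]
    submodules: dict[int, list[Submodule]]
    survival_results: pd.DataFrame | None
    info: dict = field(default_factory=dict)


def run_pipeline(
    net: PathwayNetwork,
    gene_sets: GeneSetCollection,
    cna: pd.DataFrame,
    rna_tumor: pd.DataFrame,
    rna_normal: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all eight stages on in-memory inputs."""
    cfg = config or PipelineConfig()
    info: dict = {"stages": []}

    def stage(name):
        info["stages"].append(name)
        return name

    try:
        stage("states")
        cna_st = cna_state(cna)
        ref = fit_rna_reference(rna_normal)
        rna_st = rna_state(rna_tumor, ref, k_sd=cfg.k_sd)
        patients = [str(c) for c in cna_st.columns]
    except Exception as e:  # noqa: BLE001
        raise StageError("states", e) from e

    opts = InferenceOptions(epsilon=cfg.epsilon, eta=cfg.eta)
    try:
        stage("infer")
        ipls, inf_info = infer_cohort_ipls(net, cna_st, rna_st, opts)
        info["infer"] = inf_info
    except Exception as e:  # noqa: BLE001
        raise StageError("infer", e) from e

    try:
        stage("permute")
        plan = PermutationPlan(n_perm=cfg.n_perm, seed=cfg.seed)
        perm_cna, perm_rna = generate_permutations(cna_st, rna_st, plan)
    except Exception as e:  # noqa: BLE001
        raise StageError("permute", e) from e

    try:
        stage("infer-permuted")
        if perm_cna.shape[1]:
            perm_ipls, perm_info = infer_cohort_ipls(net, perm_cna, perm_rna, opts)
            info["infer_permuted"] = perm_info
        else:
            perm_ipls = pd.DataFrame(index=ipls.index)
    except Exception as e:  # noqa: BLE001
        raise StageError("infer-permuted", e) from e

    try:
        stage("filter")
        if perm_ipls.shape[1]:
            filtered, _null = mad_filter_matrix(ipls, perm_ipls, k_mad=cfg.k_mad)
        else:
            filtered = ipls.copy()
        states, retained = pathway_states(filtered, net)
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    try:
        stage("profile")
        universe = set(net.proteins())
        source = {
            "ipl": states,
            "cna": cna_st.reindex(states.index).fillna(0.0),
            "rna": rna_st.reindex(states.index).fillna(0.0),
        }[cfg.profile_source]
        enr = overrepresentation_cohort(source, gene_sets, universe)
        profile = build_profile_matrix(enr, cap=cfg.profile_cap)
    except Exception as e:  # noqa: BLE001
        raise StageError("profile", e) from e

    try:
        stage("group")
        groups = cluster_patients(profile, k=cfg.k_groups, seed=cfg.seed)
        display = select_display_terms(
            enr.adj_p, groups, cfg.q_threshold, cfg.frac_threshold
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("group", e) from e

    try:
        stage("submodules")
        observed = (set(map(str, cna.index)) | set(map(str, rna_tumor.index))) & set(
            net.proteins()
        )
        submods: dict[int, list[Submodule]] = {}
        for g in range(1, groups.k + 1):
            members = groups.patients_in(g)
            if not members:  # a requested group may come back empty
                submods[g] = []
                continue
            subs = find_submodules(
                net,
                states,
                members,
                observed_genes=observed,
                min_size=cfg.min_submodule_size,
            )
            for s in subs:
                s.group = g
            submods[g] = subs
    except Exception as e:  # noqa: BLE001
        raise StageError("submodules", e) from e

    survival_results: pd.DataFrame | None = None
    try:
        stage("survival")
        if clinical is not None:
            rows = []
            for g, subs in submods.items():
                for si, sub in enumerate(subs):
                    keys = [p for p, _ in sub.key]
                    if not keys:
                        continue
                    strata = stratify_by_activation(ipls, keys)
                    surv = clinical.copy()
                    surv["stratum"] = strata.reindex(surv.index)
                    surv = surv.dropna(subset=["stratum"])
                    if surv["stratum"].nunique() != 2:
                        continue
                    stat, p = logrank_test(surv)
                    counts = surv["stratum"].value_counts()
                    rows.append(
                        {
                            "group": g,
                            "submodule": si,
                            "proteins": ";".join(keys),
                            "statistic": stat,
                            "p_value": p,
                            "n_activated": int(counts.get("activated", 0)),
                            "n_other": int(counts.get("other", 0)),
                        }
                    )
            survival_results = pd.DataFrame(
                rows,
                columns=[
                    "group",
                    "submodule",
                    "proteins",
                    "statistic",
                    "p_value",
                    "n_activated",
                    "n_other",
                ],
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("survival", e) from e

    return PipelineResult(
        cna_states=cna_st,
        rna_states=rna_st,
        ipls=ipls,
        perm_ipls=perm_ipls,
        filtered_ipls=filtered,
        retained=retained,
        states=states,
        enrichment_adj_p=enr.adj_p,
        profile=profile,
        groups=groups.labels,
        display_terms=display,
        submodules=submods,
        survival_results=survival_results,
        info=info,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "entity") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def run_pipeline_files(config: PipelineConfig) -> PipelineResult:
    """File-based front end: read inputs, run, write artifacts + manifest."""
    from .omic_states import read_matrix

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = parse_pathway_file(config.pathway_file)
    gene_sets = read_gmt(config.gmt_file)
    cna = read_matrix(config.cna_file)
    rna_tumor = read_matrix(config.rna_tumor_file)
    rna_normal = read_matrix(config.rna_normal_file)
    clinical = None
    if config.clinical_file:
        clinical = pd.read_csv(config.clinical_file, sep="\t", index_col=0)

    manifest = {
        "package_version": __version__,
        "parameters": asdict(config),
        "seed": config.seed,
        "input_checksums": {
            key: _sha256(path)
            for key, path in {
                "pathway": config.pathway_file,
                "gmt": config.gmt_file,
                "cna": config.cna_file,
                "rna_tumor": config.rna_tumor_file,
                "rna_normal": config.rna_normal_file,
                "clinical": config.clinical_file,
            }.items()
            if path
        },
    }

    try:
        res = run_pipeline(
            net, gene_sets, cna, rna_tumor, rna_normal, clinical, config
        )
    except StageError as e:
        manifest["failed_stage"] = e.stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    _write_tsv(res.cna_states, out / "cna_states.tsv", "gene")
    _write_tsv(res.rna_states, out / "rna_states.tsv", "gene")
    _write_tsv(res.ipls, out / "ipl.tsv")
    _write_tsv(res.filtered_ipls, out / "ipl_filtered.tsv")
    _write_tsv(res.states, out / "pathway_states.tsv")
    retained = pd.DataFrame(
        {
            p: [1 if e in comp else 0 for e in res.states.index]
            for p, comp in res.retained.items()
        },
        index=res.states.index,
    )
    _write_tsv(retained, out / "retained_component.tsv")
    _write_tsv(res.profile, out / "profile.tsv", "gene_set")
    res.groups.rename("group").to_csv(
        out / "groups.tsv", sep="\t", index_label="patient"
    )
    submods_json = {
        str(g): [
            {
                "entities": sorted(s.entities),
                "proteins": list(s.proteins),
                "observed_proteins": list(s.observed_proteins),
                "key_proteins": [
                    {"protein": p, "direction": d} for p, d in s.key
                ],
                "group": g,
            }
            for s in subs
        ]
        for g, subs in res.submodules.items()
    }
    (out / "submodules.json").write_text(
        json.dumps(submods_json, indent=2, sort_keys=True)
    )
    if res.survival_results is not None:
        res.survival_results.to_csv(
            out / "survival_results.tsv", sep="\t", index=False
        )
    manifest["stages_completed"] = res.info["stages"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return res


def split_cohort(
    samples: list[str],
    strata: dict[str, str] | pd.Series,
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified exploratory/validation split, floor rounding.

    Within each stratum, floor(fraction * n) samples go to the
    exploratory set (drawn without replacement, seeded); the rest form
    the validation set.  Empty strata are skipped with a warning.
    """
    import warnings

    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    strata = pd.Series(strata) if not isinstance(strata, pd.Series) else strata
    rng = np.random.default_rng(seed)
    exploratory: list[str] = []
    validation: list[str] = []
    levels = sorted(set(strata.loc[samples]))
    for level in levels:
        members = [s for s in samples if strata.loc[s] == level]
        if not members:
            warnings.warn(f"stratum {level!r} empty; skipped", stacklevel=2)
            continue
        n_exp = int(np.floor(fraction * len(members)))
        chosen = rng.choice(len(members), size=n_exp, replace=False)
        chosen_set = {members[i] for i in chosen}
        exploratory.extend(s for s in members if s in chosen_set)
        validation.extend(s for s in members if s not in chosen_set)
    return exploratory, validation
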