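"""Synthetic paired-source cohorts over the bundled mini-ontology.

The generative model: each participant carries a gene whose phenotype
profile spreads terms across body systems; each source (PRD/CRD) detects
each latent term with a per-system, per-source probability; a detected term
is reported exactly with the source's specificity, otherwise blurred to an
ancestor a geometric number of levels up (truncated at the system branch
root); unrelated common-phenotype noise terms are appended at a per-source
Poisson rate.  Ground truth for every event is returned alongside the
cohort, so parameter-recovery tests can check the pipeline end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_data import Cohort, ParticipantMeta, PhenotypeRecord
from .errors import ValidationError
from .ontology import OntologyGraph, load_obo
from .scores import score_table
from .stats import counts_from_scores, mcnemar_family

#: top-level fixture term anchoring each body-system branch
SYSTEM_ROOTS = {
    "cardiac": "HP:0001626",
    "dental": "HP:0000164",
    "endocrine": "HP:0000818",
    "ENT": "HP:0000598",
    "gastroenterology": "HP:0025031",
    "immunology": "HP:0002715",
    "neurology": "HP:0000707",
    "renal": "HP:0000077",
    "respiratory": "HP:0002086",
    "vision": "HP:0000478",
}

#: common-childhood-phenotype pool used for unrelated noise injections
NOISE_POOL = [
    ("respiratory", "HP:0002099"),   # asthma
    ("respiratory", "HP:0025267"),   # snoring
    ("respiratory", "HP:0001742"),   # nasal congestion
    ("respiratory", "HP:0002205"),   # recurrent respiratory infections
    ("gastroenterology", "HP:0002019"),  # constipation
    ("gastroenterology", "HP:0002020"),  # reflux
    ("dental", "HP:0000670"),        # carious teeth
    ("dental", "HP:0000684"),        # delayed eruption of teeth
    ("ENT", "HP:0000388"),           # otitis media
    ("immunology", "HP:0002719"),    # recurrent infections
]


def fixture_obo_path() -> Path:
    return Path(resources.files("phenocompare").joinpath("data/mini_hpo.obo"))


def make_fixture_ontology() -> OntologyGraph:
    """Load the bundled ~55-term mini-ontology (intrinsic IC precomputed)."""
    return load_obo(fixture_obo_path(), root="HP:0000001")


def system_pool(
    graph: OntologyGraph, system: str, leaves_only: bool = False
) -> list[str]:
    """Reportable terms for a system: proper descendants of its branch root.

    With ``leaves_only`` only terms without children are returned; latent
    profiles use these so that blurring (exact term -> ancestor) is the only
    way coarser terms enter a report.
    """
    if system not in SYSTEM_ROOTS:
        raise ValidationError(f"unknown system {system!r}")
    branch = SYSTEM_ROOTS[system]
    members = [t for t in graph.terms if branch in graph.ancestor_closure[t]]
    if leaves_only:
        has_child = {p for t in graph.terms.values() for p in t.parent_ids}
        members = [t for t in members if t not in has_child]
    return sorted(members)


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    group: str
    profile_size: int


@dataclass
class SimConfig:
    seed: int = 0
    n_participants: int = 100
    genes: list[GeneSpec] = field(
        default_factory=lambda: [
            GeneSpec("GENE1", "chromatin", 8),
            GeneSpec("GENE2", "chromatin", 8),
            GeneSpec("GENE3", "transporter", 8),
            GeneSpec("GENE4", "transporter", 8),
            GeneSpec("GENE5", "scaffold", 8),
            GeneSpec("GENE6", "scaffold", 8),
        ]
    )
    systems: list[str] = field(
        default_factory=lambda: ["neurology", "gastroenterology", "vision", "respiratory"]
    )
    detect: dict[tuple[str, str], float] = field(default_factory=dict)
    default_detect: float = 0.7
    specificity: dict[str, float] = field(
        default_factory=lambda: {"PRD": 0.8, "CRD": 0.8}
    )
    blur_depth: float = 0.7
    noise_rate: dict[str, float] = field(
        default_factory=lambda: {"PRD": 0.0, "CRD": 0.0}
    )
    penetrance: float = 1.0
    profile_leaves_only: bool = True

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        probs = (
            list(self.detect.values())
            + [self.default_detect, self.penetrance]
            + list(self.specificity.values())
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if not (0 < self.blur_depth <= 1):
            raise ValidationError("blur_depth must lie in (0, 1]")

    def detect_p(self, system: str, source: str) -> float:
        return self.detect.get((system, source), self.default_detect)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["genes"] = [dataclasses.asdict(g) for g in self.genes]
        d["detect"] = {f"{s}|{src}": p for (s, src), p in self.detect.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["genes"] = [GeneSpec(**g) for g in d.get("genes", [])]
        d["detect"] = {
            tuple(k.split("|")): v for k, v in d.get("detect", {}).items()
        }
        return cls(**d)


@dataclass
class GroundTruth:
    latent: pd.DataFrame     # participant_id, gene, system, term_id
    events: pd.DataFrame     # participant_id, source, system, latent_term, detected, reported_term, blur_steps
    noise: pd.DataFrame      # participant_id, source, system, term_id


def _gene_profiles(
    graph: OntologyGraph, config: SimConfig, rng: np.random.Generator
) -> dict[str, list[tuple[str, str]]]:
    """Per-gene latent profiles as (system, term) pairs, systems round-robin."""
    pools = {
        s: system_pool(graph, s, leaves_only=config.profile_leaves_only)
        for s in config.systems
    }
    for s, pool in pools.items():
        if not pool:
            raise ValidationError(f"empty profile pool for system {s!r}")
    profiles: dict[str, list[tuple[str, str]]] = {}
    for gene in config.genes:
        per_system: dict[str, int] = {s: 0 for s in config.systems}
        for i in range(gene.profile_size):
            per_system[config.systems[i % len(config.systems)]] += 1
        items: list[tuple[str, str]] = []
        for s in config.systems:
            k = min(per_system[s], len(pools[s]))
            if k == 0:
                continue
            chosen = rng.choice(len(pools[s]), size=k, replace=False)
            items.extend((s, pools[s][j]) for j in sorted(chosen))
        if not items:
            raise ValidationError(f"empty profile for gene {gene.symbol!r}")
        profiles[gene.symbol] = items
    return profiles


def _blur(
    graph: OntologyGraph,
    term: str,
    branch_root: str,
    steps: int,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Walk up to ``steps`` parent edges, staying inside the branch."""
    current = term
    taken = 0
    for _ in range(steps):
        if current == branch_root:
            break
        candidates = sorted(
            p
            for p in graph.terms[current].parent_ids
            if p == branch_root or branch_root in graph.ancestor_closure[p]
        )
        if not candidates:
            break
        current = candidates[int(rng.integers(len(candidates)))]
        taken += 1
    return current, taken


def simulate_cohort(
    graph: OntologyGraph, config: SimConfig
) -> tuple[Cohort, GroundTruth]:
    """Generate a paired-source cohort plus event-level ground truth."""
    rng = np.random.default_rng(config.seed)
    profiles = _gene_profiles(graph, config, rng)
    noise_pool = [(s, t) for s, t in NOISE_POOL if s in config.systems]

    latent_rows, event_rows, noise_rows = [], [], []
    record_keys: set[tuple[str, str, str, str]] = set()
    records: list[PhenotypeRecord] = []
    meta: dict[str, ParticipantMeta] = {}

    def add_record(pid: str, source: str, system: str, term: str) -> None:
        key = (pid, source, system, term)
        if key not in record_keys:
            record_keys.add(key)
            records.append(PhenotypeRecord(pid, source, system, term))

    width = max(4, len(str(config.n_participants)))
    for i in range(config.n_participants):
        pid = f"P{i:0{width}d}"
        gene = config.genes[int(rng.integers(len(config.genes)))]
        meta[pid] = ParticipantMeta(pid, gene.symbol, gene.group)
        latent = [
            (s, t)
            for s, t in profiles[gene.symbol]
            if config.penetrance >= 1.0 or rng.random() < config.penetrance
        ]
        for s, t in latent:
            latent_rows.append((pid, gene.symbol, s, t))
        for source in ("PRD", "CRD"):
            sigma = config.specificity[source]
            for system, term in latent:
                detected = rng.random() < config.detect_p(system, source)
                reported, steps = None, 0
                if detected:
                    if rng.random() < sigma:
                        reported = term
                    else:
                        k = int(rng.geometric(config.blur_depth))
                        reported, steps = _blur(
                            graph, term, SYSTEM_ROOTS[system], k, rng
                        )
                    add_record(pid, source, system, reported)
                event_rows.append(
                    (pid, source, system, term, detected, reported, steps)
                )
            rate = config.noise_rate.get(source, 0.0)
            if rate > 0 and noise_pool:
                for _ in range(int(rng.poisson(rate))):
                    system, term = noise_pool[int(rng.integers(len(noise_pool)))]
                    noise_rows.append((pid, source, system, term))
                    add_record(pid, source, system, term)

    cohort = Cohort(records=records, meta=meta, systems=tuple(config.systems))
    truth = GroundTruth(
        latent=pd.DataFrame(
            latent_rows, columns=["participant_id", "gene", "system", "term_id"]
        ),
        events=pd.DataFrame(
            event_rows,
            columns=[
                "participant_id",
                "source",
                "system",
                "latent_term",
                "detected",
                "reported_term",
                "blur_steps",
            ],
        ),
        noise=pd.DataFrame(
            noise_rows, columns=["participant_id", "source", "system", "term_id"]
        ),
    )
    return cohort, truth


def replicate_mcnemar(
    graph: OntologyGraph,
    config: SimConfig,
    scope: str,
    value: str,
    n_replicates: int,
    alpha: float = 0.05,
    continuity: bool = True,
) -> pd.DataFrame:
    """Per-replicate McNemar outcomes for one scope of the simulated pipeline.

    Each replicate reseeds the generator (config.seed + index), simulates a
    cohort, scores it, tallies Parent-more/Doctor-more and runs McNemar with
    BH adjustment within the single-scope family.
    """
    rows = []
    from .scores import scores_to_frame

    for rep in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + rep)
        cohort, _ = simulate_cohort(graph, cfg)
        scores = scores_to_frame(score_table(cohort, graph, [scope]))
        counts = counts_from_scores(scores, value=value)
        cc = counts.get(scope)
        if cc is None or (cc.n_parent_more + cc.n_doctor_more) == 0:
            rows.append((rep, np.nan, np.nan, 0, 0, 0, False, ""))
            continue
        (result,) = mcnemar_family([cc], family=f"{value}:{scope}", continuity=continuity)
        majority = (
            "Parent more"
            if cc.n_parent_more > cc.n_doctor_more
            else "Doctor more"
            if cc.n_doctor_more > cc.n_parent_more
            else "tie"
        )
        rows.append(
            (
                rep,
                result.p_raw,
                result.p_adjusted,
                cc.n_parent_more,
                cc.n_doctor_more,
                cc.n_equal,
                bool(result.p_adjusted is not None and result.p_adjusted < alpha),
                majority,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "p_raw",
            "p_adjusted",
            "n_parent_more",
            "n_doctor_more",
            "n_equal",
            "reject",
            "majority",
        ],
    )


def recovery_experiment(
    graph: OntologyGraph,
    config_grid: dict[str, SimConfig],
    scope: str = "combined",
    value: str = "quantity",
    n_replicates: int = 50,
    alpha: float = 0.05,
    continuity: bool = True,
) -> pd.DataFrame:
    """Directional-recovery report over a grid of simulation configs.

    For each named config: the McNemar rejection rate at ``alpha`` and the
    fraction of replicates in which each category holds the majority of
    discordant participants.
    """
    rows = []
    for name, config in config_grid.items():
        reps = replicate_mcnemar(
            graph, config, scope, value, n_replicates, alpha, continuity
        )
        rows.append(
            {
                "config": name,
                "scope": scope,
                "value": value,
                "n_replicates": n_replicates,
                "rejection_rate": float(reps["reject"].mean()),
                "parent_more_majority_rate": float((reps["majority"] == "Parent more").mean()),
                "doctor_more_majority_rate": float((reps["majority"] == "Doctor more").mean()),
                "mean_parent_more": float(reps["n_parent_more"].mean()),
                "mean_doctor_more": float(reps["n_doctor_more"].mean()),
            }
        )
    return pd.DataFrame(rows)
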