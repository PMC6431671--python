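"""Synthetic datasets with planted ground truth for every pipeline stage.

Real inputs to this pipeline (reporter-ion spectra, compound fingerprint
libraries, interaction networks, pathway sets) come from instruments and
curated databases that cannot be redistributed.  These generators emulate
their statistical shape with known planted truth so every downstream stage
is testable end to end:

* ``gen_itraq_dataset`` — a 4-plex reporter-area table over batches of
  three cases and one control, with planted up/down-regulated proteins and
  lognormal multiplicative peptide noise (reporter ratios are strictly
  positive, so multiplicative noise is the natural model);
* ``gen_compound_library`` — binary fingerprints with a planted subset
  constructed to exceed Tanimoto 0.8 against a reference-drug set;
* ``gen_ppi_and_pathways`` — a scale-free-like interaction network with
  Beta-distributed combined scores, a planted overrepresented pathway,
  compound→target annotations and a disease-target list;
* ``gen_key_target_scenario`` — the integration-stage shape: predicted
  hubs and experimental DEP lists whose intersection hides a few planted
  high-centrality key targets.

Every generator is a pure function of its config and seed: the same seed
yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .itraq import ConfigurationError


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# iTRAQ reporter-area tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItraqSimConfig:
    """Design of a simulated 4-plex experiment.

    Channels 115-117 carry case sera, channel 114 the pooled control, so
    ``n_batches`` x ``patients_per_batch`` gives the total patient count
    (default 10 x 3 = 30).  The number of planted regulated proteins is
    round(frac x n_proteins), up-regulated planted first — counts are exact,
    not in expectation.
    """

    n_proteins: int = 500
    frac_up: float = 0.1
    frac_down: float = 0.1
    up_fold: float = 2.0
    down_fold: float = 0.5
    peptides_min: int = 2
    peptides_max: int = 6
    noise_cv: float = 0.2
    n_batches: int = 10
    patients_per_batch: int = 3
    batch_effect_sd: float = 0.0
    baseline_area: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ConfigurationError("frac_up + frac_down must not exceed 1")
        if not (self.down_fold < 1 < self.up_fold) or self.down_fold <= 0:
            raise ConfigurationError(
                "folds must satisfy up_fold > 1 > down_fold > 0"
            )
        if self.up_fold <= 1.2 or self.down_fold >= 0.8:
            raise ConfigurationError(
                "planted folds must clear the calling thresholds "
                "(up_fold > 1.2, down_fold < 0.8)"
            )
        if not (1 <= self.peptides_min <= self.peptides_max):
            raise ConfigurationError("need 1 <= peptides_min <= peptides_max")
        if self.noise_cv < 0 or self.n_batches < 1 or self.patients_per_batch < 1:
            raise ConfigurationError("noise_cv >= 0 and positive counts required")
        if self.patients_per_batch > 3:
            raise ConfigurationError("a 4-plex batch holds at most 3 case channels")


def gen_itraq_dataset(cfg: ItraqSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a reporter-area spectra table plus its planted truth table.

    Returns (spectra, truth).  Spectra columns: peptide_id, protein_acc,
    batch, area_114..area_117, protein_score, unused_score — one row per
    (peptide, batch).  Truth columns: protein_acc, direction (up/down/null),
    true_fold.  Channel-114 areas scatter around a per-protein baseline;
    case channels are scaled by true_fold times unit-mean lognormal noise
    with the configured CV.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    n_up = round(cfg.frac_up * n)
    n_down = round(cfg.frac_down * n)
    if n_up + n_down > n:  # rounding can overshoot at the boundary; up wins
        n_down = n - n_up

    accs = [f"SIM{i:05d}" for i in range(n)]
    directions = ["up"] * n_up + ["down"] * n_down + ["null"] * (n - n_up - n_down)
    folds = np.where(
        np.array(directions) == "up", cfg.up_fold,
        np.where(np.array(directions) == "down", cfg.down_fold, 1.0),
    )
    truth = pd.DataFrame(
        {"protein_acc": accs, "direction": directions, "true_fold": folds}
    )

    n_peps = rng.integers(cfg.peptides_min, cfg.peptides_max + 1, size=n)
    baselines = cfg.baseline_area * rng.lognormal(0.0, 0.5, size=n)
    batch_scale = (
        np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_batches))
        if cfg.batch_effect_sd > 0
        else np.ones(cfg.n_batches)
    )

    case_channels = (115, 116, 117)[: cfg.patients_per_batch]
    rows: dict[str, list] = {c: [] for c in (
        "peptide_id", "protein_acc", "batch",
        *(f"area_{ch}" for ch in (114, 115, 116, 117)),
        "protein_score", "unused_score",
    )}
    for i, acc in enumerate(accs):
        protein_score = float(5.0 + 2.0 * n_peps[i])
        unused_score = float(2.0 + 1.5 * n_peps[i])
        for p in range(n_peps[i]):
            pep_id = f"{acc}_pep{p:02d}"
            pep_base = baselines[i] * float(_lognormal_factors(rng, 0.3, None))
            for b in range(1, cfg.n_batches + 1):
                scale = pep_base * batch_scale[b - 1]
                a114 = scale * float(_lognormal_factors(rng, cfg.noise_cv, None))
                areas = {114: a114}
                for ch in case_channels:
                    areas[ch] = (
                        scale * folds[i]
                        * float(_lognormal_factors(rng, cfg.noise_cv, None))
                    )
                for ch in (115, 116, 117):
                    areas.setdefault(ch, 0.0)
                rows["peptide_id"].append(pep_id)
                rows["protein_acc"].append(acc)
                rows["batch"].append(b)
                for ch in (114, 115, 116, 117):
                    rows[f"area_{ch}"].append(areas[ch])
                rows["protein_score"].append(protein_score)
                rows["unused_score"].append(unused_score)
    spectra = pd.DataFrame(rows)
    return spectra, truth


# ---------------------------------------------------------------------------
# compound fingerprint libraries
# ---------------------------------------------------------------------------

def gen_compound_library(
    n_compounds: int,
    fp_length: int = 64,
    n_similar: int = 0,
    seed: int = 0,
    n_references: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary fingerprint library with a planted Tanimoto-similar subset.

    Returns (library, references).  Exactly ``n_similar`` compounds are
    built by copying a reference fingerprint and flipping at most as many
    bits as keeps Tanimoto strictly above 0.8; the remainder are rejection-
    sampled to score strictly below 0.8 against every reference.  Library
    columns: compound_id, fingerprint (bitstring), tanimoto_truth (0/1).
    """
    if fp_length < 8:
        raise ConfigurationError("fp_length must be >= 8")
    if not (0 <= n_similar <= n_compounds):
        raise ConfigurationError("need 0 <= n_similar <= n_compounds")
    rng = np.random.default_rng(seed)
    n_on = fp_length // 2

    def random_fp() -> np.ndarray:
        fp = np.zeros(fp_length, dtype=bool)
        fp[rng.choice(fp_length, size=n_on, replace=False)] = True
        return fp

    refs = [random_fp() for _ in range(n_references)]

    def tani(a, b):
        u = int(np.sum(a | b))
        return int(np.sum(a & b)) / u if u else 0.0

    lib_rows = []
    for i in range(n_compounds):
        cid = f"C{i:04d}"
        if i < n_similar:
            ref = refs[int(rng.integers(n_references))]
            fp = ref.copy()
            # swapping one on-bit for one off-bit keeps T = (b-1)/(b+1);
            # only allowed when that still clears 0.8, else emit an exact copy
            if (n_on - 1) / (n_on + 1) > 0.8 and rng.random() < 0.5:
                on = np.flatnonzero(fp)
                off = np.flatnonzero(~fp)
                fp[rng.choice(on)] = False
                fp[rng.choice(off)] = True
            assert max(tani(fp, r) for r in refs) > 0.8
            label = 1
        else:
            for _ in range(1000):
                fp = random_fp()
                if max(tani(fp, r) for r in refs) < 0.8:
                    break
            else:
                raise ConfigurationError(
                    "fp_length too small to sample dissimilar fingerprints"
                )
            label = 0
        lib_rows.append(
            {
                "compound_id": cid,
                "fingerprint": "".join("1" if b else "0" for b in fp),
                "tanimoto_truth": label,
            }
        )
    library = pd.DataFrame(lib_rows)
    references = pd.DataFrame(
        {
            "compound_id": [f"REF{j:02d}" for j in range(n_references)],
            "fingerprint": ["".join("1" if b else "0" for b in r) for r in refs],
        }
    )
    return library, references


# ---------------------------------------------------------------------------
# interaction networks, pathways, target lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSimConfig:
    """Design of a simulated target network with planted structure."""

    n_targets: int = 240
    n_disease_targets: int = 134
    n_compounds: int = 20
    n_overlap: int = 30
    edge_model: str = "preferential-attachment"
    score_beta_params: tuple[float, float] = (4.0, 2.0)
    planted_pathway_size: int = 10
    n_decoy_pathways: int = 20
    targets_per_compound: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_targets, self.n_disease_targets):
            raise ConfigurationError(
                "n_overlap must not exceed either target-list size"
            )
        a, b = self.score_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("score_beta_params must be positive")
        if self.edge_model not in ("preferential-attachment", "configuration"):
            raise ConfigurationError(f"unknown edge_model {self.edge_model!r}")


def gen_ppi_and_pathways(cfg: NetworkSimConfig) -> dict:
    """Simulate PPI edges, pathway sets, compound→target and disease lists.

    Returns a dict with keys ``edges`` (node_a, node_b, combined_score),
    ``pathways`` (pathway_id -> gene set; ``PLANTED`` is a clique-like set
    over the highest-degree nodes), ``planted_pathway`` (its id),
    ``compound_targets`` (compound_id, target_id), ``disease_targets``
    (list) and ``putative_targets`` (list).  Scores are i.i.d.
    Beta(a, b); the graph is preferential-attachment (heavy-tailed
    degrees) or a configuration-model variant.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_targets)]
    putative = genes
    disease = genes[: cfg.n_overlap] + [
        f"D{i:05d}" for i in range(cfg.n_disease_targets - cfg.n_overlap)
    ]
    universe = sorted(set(putative) | set(disease))
    n_nodes = len(universe)

    if cfg.edge_model == "preferential-attachment":
        g = nx.barabasi_albert_graph(n_nodes, 2, seed=int(rng.integers(2**31)))
    else:
        deg_seq = rng.integers(1, 6, size=n_nodes)
        if deg_seq.sum() % 2:
            deg_seq[0] += 1
        g = nx.configuration_model(deg_seq, seed=int(rng.integers(2**31)))
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
    relabel = dict(enumerate(universe))
    g = nx.relabel_nodes(g, relabel)

    # plant a clique-like pathway among the highest-degree nodes so it is
    # both topologically central and overrepresented in hub queries
    by_degree = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    planted = sorted(n for n, _ in by_degree[: cfg.planted_pathway_size])
    for i, u in enumerate(planted):
        for v in planted[i + 1:]:
            g.add_edge(u, v)

    a, b = cfg.score_beta_params
    edges = pd.DataFrame(
        [(u, v) for u, v in sorted(g.edges())], columns=["node_a", "node_b"]
    )
    edges["combined_score"] = rng.beta(a, b, size=len(edges))

    pathways = {"PLANTED": frozenset(planted)}
    for j in range(cfg.n_decoy_pathways):
        size = int(rng.integers(5, 25))
        members = rng.choice(universe, size=size, replace=False)
        pathways[f"PW{j:03d}"] = frozenset(members)

    compound_targets = pd.DataFrame(
        [
            (f"C{c:04d}", t)
            for c in range(cfg.n_compounds)
            for t in rng.choice(
                putative,
                size=min(cfg.targets_per_compound, len(putative)),
                replace=False,
            )
        ],
        columns=["compound_id", "target_id"],
    )
    return {
        "edges": edges,
        "pathways": pathways,
        "planted_pathway": "PLANTED",
        "compound_targets": compound_targets,
        "disease_targets": sorted(disease),
        "putative_targets": sorted(putative),
        "universe": universe,
    }


# ---------------------------------------------------------------------------
# integration-stage scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyTargetScenario:
    """Planted integration inputs: hub/DEP lists sharing a few key targets."""

    hubs: list[str]
    deps: list[str]
    edges: pd.DataFrame = field(repr=False)
    planted_keys: list[str] = field(default_factory=list)


def gen_key_target_scenario(
    n_hubs: int = 12,
    n_deps: int = 13,
    n_key: int = 3,
    seed: int = 0,
    key_score: float = 0.9,
    background_score: float = 0.3,
    score_jitter: float = 0.05,
) -> KeyTargetScenario:
    """Build hub/DEP candidate lists with planted high-centrality key targets.

    The ``n_key`` key targets belong to both lists (the intersection) and are
    wired to every other merged candidate with high-confidence edges; the
    remaining candidates carry only low-confidence background edges (a ring
    plus random chords, all at exactly ``background_score``).  Background
    edges outnumber the high-confidence ones, so the score median sits at
    the background level and the strict median filter removes precisely the
    background, leaving the planted nodes dominating degree, betweenness
    and closeness.
    """
    if n_key > min(n_hubs, n_deps):
        raise ConfigurationError("n_key must fit inside both candidate lists")
    if not background_score < key_score - score_jitter:
        raise ConfigurationError("key and background score bands must not overlap")
    rng = np.random.default_rng(seed)
    keys = [f"KEY{i}" for i in range(n_key)]
    hubs = keys + [f"HUB{i:02d}" for i in range(n_hubs - n_key)]
    deps = keys + [f"DEP{i:02d}" for i in range(n_deps - n_key)]
    others = hubs[n_key:] + deps[n_key:]

    key_rows = []
    for k in keys:
        for node in others:
            key_rows.append((k, node))
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            key_rows.append((a, b))

    bg_pairs = {(a, others[(i + 1) % len(others)]) for i, a in enumerate(others)}
    bg_pairs = {tuple(sorted(p)) for p in bg_pairs if p[0] != p[1]}
    all_chords = [
        (a, b)
        for i, a in enumerate(others)
        for b in others[i + 1:]
        if (a, b) not in bg_pairs
    ]
    n_extra = max(0, len(key_rows) + 1 - len(bg_pairs))
    if n_extra > len(all_chords):
        raise ConfigurationError("too few background candidates to outnumber keys")
    picked = rng.choice(len(all_chords), size=n_extra, replace=False)
    bg_rows = sorted(bg_pairs) + [all_chords[i] for i in sorted(picked)]

    rows = [
        (a, b, float(np.clip(key_score + rng.uniform(-score_jitter, score_jitter),
                             0.0, 1.0)))
        for a, b in key_rows
    ] + [(a, b, background_score) for a, b in bg_rows]
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])
    return KeyTargetScenario(hubs=hubs, deps=deps, edges=edges, planted_keys=keys)
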