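"""Mutational-signature feature selection from single-base substitutions.

Somatic substitutions are encoded into the standard 96 trinucleotide
categories (6 pyrimidine-centered substitution classes x 4 flanking 5' bases
x 4 flanking 3' bases, COSMIC lexicographic order).  Each sample's mutation
list, sorted along the genome, is split into *close* runs (consecutive
mutations at most 2000 bp apart; the first mutation of a sample, and the
first on each chromosome, is close by convention) and *isolated* runs.

Close runs are modeled with a hidden Markov model over t signature states
(start probabilities pi, transition matrix A, emission matrix E over the 96
categories); isolated mutations with a multinomial mixture (mixing vector g
sharing the emission matrix shape).  Parameters are estimated by EM
(Baum-Welch for the HMM, with multi-restart; responsibility EM for the
mixture).  By default emissions are *fixed* to user-supplied reference
signature profiles so states correspond to named signatures; free-emission
fitting is available.

Per sample, the Viterbi path over each close run and the posterior-argmax
state of each isolated mutation are reassembled in genomic order; the
per-state occurrence counts are the sample's *signature activities*.  Genes
whose expression has Spearman correlation > 0.2 (configurable; signed by
default) with any signature activity across samples are selected as
mutation features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

N_CATEGORIES = 96
BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_SUB_IDX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

CLOSE_THRESHOLD_BP = 2000
EMISSION_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# 96-category encoding
# ---------------------------------------------------------------------------

def categorize_mutation(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Map a single-base substitution with its trinucleotide context to its
    category index in [0, 95].

    Purine-reference mutations are reverse-complemented to the
    pyrimidine-centered convention (the 5'/3' flanks swap and complement).
    Ordering is COSMIC lexicographic: substitution class major, then the 5'
    base, then the 3' base, each in A<C<G<T order.
    """
    for b in (ref, alt, five_prime, three_prime):
        if b not in _COMP:
            raise ValueError(f"invalid DNA base: {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # purine reference: flip strand
        ref, alt = _COMP[ref], _COMP[alt]
        five_prime, three_prime = _COMP[three_prime], _COMP[five_prime]
    sub = f"{ref}>{alt}"
    return _SUB_IDX[sub] * 16 + _BASE_IDX[five_prime] * 4 + _BASE_IDX[three_prime]


def category_context(category: int) -> tuple[str, str, str, str]:
    """Inverse of :func:`categorize_mutation` on the pyrimidine-centered
    domain: returns (ref, alt, five_prime, three_prime)."""
    if not 0 <= category < N_CATEGORIES:
        raise ValueError("category out of range")
    sub, rem = divmod(category, 16)
    five, three = divmod(rem, 4)
    ref, alt = SUBSTITUTIONS[sub].split(">")
    return ref, alt, BASES[five], BASES[three]


def category_labels() -> list[str]:
    """The 96 category names, e.g. ``A[C>A]A``, in encoding order."""
    out = []
    for c in range(N_CATEGORIES):
        ref, alt, five, three = category_context(c)
        out.append(f"{five}[{ref}>{alt}]{three}")
    return out


def categorize_table(maf: pd.DataFrame) -> pd.DataFrame:
    """Add a ``category`` column to a MAF-like table with columns
    sample, chrom, pos, ref, alt, context5, context3."""
    cats = [categorize_mutation(r, a, f5, f3) for r, a, f5, f3 in
            zip(maf["ref"], maf["alt"], maf["context5"], maf["context3"])]
    out = maf.copy()
    out["category"] = cats
    return out


# ---------------------------------------------------------------------------
# close / isolated partition
# ---------------------------------------------------------------------------

@dataclass
class Run:
    kind: str                  # "close" | "isolated"
    categories: np.ndarray     # int categories, genomic order
    positions: np.ndarray
    chromosome: str = "1"


@dataclass
class MutationPartition:
    sample_id: str
    runs: list[Run]

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """(categories, positions) restored in genomic order."""
        if not self.runs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        cats = np.concatenate([r.categories for r in self.runs])
        pos = np.concatenate([r.positions for r in self.runs])
        return cats, pos

    @property
    def n_mutations(self) -> int:
        return sum(len(r.categories) for r in self.runs)

    def close_runs(self) -> list[np.ndarray]:
        return [r.categories for r in self.runs if r.kind == "close"]

    def isolated_categories(self) -> np.ndarray:
        iso = [r.categories for r in self.runs if r.kind == "isolated"]
        return np.concatenate(iso) if iso else np.empty(0, dtype=int)


def split_close_isolated(events: pd.DataFrame,
                         threshold_bp: int = CLOSE_THRESHOLD_BP) -> MutationPartition:
    """Partition one sample's sorted mutations into maximal close/isolated
    runs.

    The first mutation of the sample — and the first on each chromosome —
    is labeled close; every later mutation is close iff its distance to the
    previous mutation on the same chromosome is <= ``threshold_bp`` (a gap
    of exactly the threshold is close; isolated requires a strictly greater
    gap).
    """
    required = {"chrom", "pos", "category"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    sample_id = str(events["sample"].iloc[0]) if "sample" in events.columns and len(events) else ""
    chroms = events["chrom"].astype(str).to_numpy()
    pos = events["pos"].to_numpy(dtype=np.int64)
    cats = events["category"].to_numpy(dtype=int)
    for i in range(1, len(events)):
        if chroms[i] == chroms[i - 1] and pos[i] < pos[i - 1]:
            raise ValueError("events must be sorted by (chromosome, position)")
    runs: list[Run] = []
    cur_kind, cur_cats, cur_pos, cur_chrom = None, [], [], None
    for i in range(len(events)):
        if i == 0 or chroms[i] != chroms[i - 1]:
            kind = "close"  # first mutation of a (chromosome) sequence
        else:
            kind = "close" if pos[i] - pos[i - 1] <= threshold_bp else "isolated"
        if kind != cur_kind or chroms[i] != cur_chrom:
            if cur_kind is not None:
                runs.append(Run(cur_kind, np.array(cur_cats, dtype=int),
                                np.array(cur_pos, dtype=np.int64), cur_chrom))
            cur_kind, cur_cats, cur_pos, cur_chrom = kind, [], [], chroms[i]
        cur_cats.append(cats[i])
        cur_pos.append(pos[i])
    if cur_kind is not None:
        runs.append(Run(cur_kind, np.array(cur_cats, dtype=int),
                        np.array(cur_pos, dtype=np.int64), cur_chrom))
    return MutationPartition(sample_id, runs)


def partition_samples(maf: pd.DataFrame,
                      threshold_bp: int = CLOSE_THRESHOLD_BP) -> dict[str, MutationPartition]:
    """Categorize and partition a full MAF-like table, one partition per
    sample.  Mutations are sorted by (chromosome, position) per sample."""
    table = categorize_table(maf) if "category" not in maf.columns else maf
    out: dict[str, MutationPartition] = {}
    for sample, sub in table.groupby("sample", sort=True):
        sub = sub.sort_values(["chrom", "pos"], kind="stable")
        part = split_close_isolated(sub, threshold_bp)
        part.sample_id = str(sample)
        out[str(sample)] = part
    return out


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _check_simplex(v: np.ndarray, name: str, axis: int | None = None) -> None:
    v = np.asarray(v)
    if (v < -1e-12).any():
        raise ValueError(f"{name} has negative entries")
    sums = v.sum() if axis is None else v.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must sum to 1")


@dataclass
class HmmModel:
    """Hidden Markov model over t signature states emitting 96 categories."""

    pi: np.ndarray
    A: np.ndarray
    E: np.ndarray
    emissions_fixed: bool = False
    log_likelihood: float = float("nan")
    converged: bool = True
    loglik_trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        t = self.pi.shape[0]
        if self.A.shape != (t, t) or self.E.shape[0] != t:
            raise ValueError("inconsistent HMM dimensions")
        _check_simplex(self.pi, "pi")
        _check_simplex(self.A, "A", axis=1)
        _check_simplex(self.E, "E", axis=1)

    @property
    def t(self) -> int:
        return self.pi.shape[0]


@dataclass
class MmmModel:
    """Multinomial mixture over t signature components."""

    g: np.ndarray
    E: np.ndarray
    emissions_fixed: bool = False
    log_likelihood: float = float("nan")
    converged: bool = True
    loglik_trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape[0] != self.g.shape[0]:
            raise ValueError("inconsistent MMM dimensions")
        _check_simplex(self.g, "g")
        _check_simplex(self.E, "E", axis=1)

    @property
    def t(self) -> int:
        return self.g.shape[0]


def floor_emissions(E: np.ndarray, floor: float = EMISSION_FLOOR) -> np.ndarray:
    """Floor zero emission probabilities before log-space use and
    renormalize rows; flooring is logged."""
    E = np.asarray(E, dtype=float)
    n_zero = int((E < floor).sum())
    if n_zero:
        logger.info("floor_emissions: floored %d entries at %g", n_zero, floor)
        E = np.maximum(E, floor)
        E = E / E.sum(axis=1, keepdims=True)
    return E


# ---------------------------------------------------------------------------
# forward / backward / Viterbi
# ---------------------------------------------------------------------------

def forward_logprob(model: HmmModel, run: Sequence[int]) -> float:
    """Scaled forward algorithm: log P(run | model)."""
    obs = np.asarray(run, dtype=int)
    if obs.size == 0:
        raise ValueError("run must be nonempty")
    E = model.E
    alpha = model.pi * E[:, obs[0]]
    total = alpha.sum()
    if total == 0.0:
        raise ValueError("zero-probability sequence at position 0")
    loglik = np.log(total)
    alpha /= total
    for tau in range(1, obs.size):
        alpha = (alpha @ model.A) * E[:, obs[tau]]
        total = alpha.sum()
        if total == 0.0:
            raise ValueError(f"zero-probability sequence at position {tau}")
        loglik += np.log(total)
        alpha /= total
    return float(loglik)


def viterbi(model: HmmModel, run: Sequence[int]) -> np.ndarray:
    """Most likely state path (log-space dynamic program).  Ties are broken
    toward the lower state index at every step."""
    obs = np.asarray(run, dtype=int)
    if obs.size == 0:
        raise ValueError("run must be nonempty")
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_A = np.log(model.A)
        log_E = np.log(model.E)
    T, t = obs.size, model.t
    delta = log_pi + log_E[:, obs[0]]
    if np.isneginf(delta).all():
        raise ValueError("zero-probability sequence at position 0")
    back = np.zeros((T, t), dtype=int)
    for tau in range(1, T):
        scores = delta[:, None] + log_A            # (from, to)
        back[tau] = np.argmax(scores, axis=0)      # argmax -> lowest index on ties
        delta = scores[back[tau], np.arange(t)] + log_E[:, obs[tau]]
        if np.isneginf(delta).all():
            raise ValueError(f"zero-probability sequence at position {tau}")
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for tau in range(T - 2, -1, -1):
        path[tau] = back[tau + 1][path[tau + 1]]
    return path


def viterbi_score(model: HmmModel, path: Sequence[int], run: Sequence[int]) -> float:
    """Log joint probability of a (state path, observation) pair."""
    path = np.asarray(path, dtype=int)
    obs = np.asarray(run, dtype=int)
    with np.errstate(divide="ignore"):
        s = np.log(model.pi[path[0]]) + np.log(model.E[path[0], obs[0]])
        for tau in range(1, obs.size):
            s += np.log(model.A[path[tau - 1], path[tau]])
            s += np.log(model.E[path[tau], obs[tau]])
    return float(s)


# ---------------------------------------------------------------------------
# Baum-Welch (batched over equal-length run groups)
# ---------------------------------------------------------------------------

def _batch_e_step(obs: np.ndarray, pi: np.ndarray, A: np.ndarray, E: np.ndarray):
    """Forward-backward for a batch of equal-length runs.

    obs: (R, T) int.  Returns (loglik, gamma1_sum, xi_sum, emit_counts)
    where gamma1_sum is the summed start-state posterior, xi_sum the summed
    expected transition counts, emit_counts the (t, 96) expected emission
    counts.
    """
    R, T = obs.shape
    t = pi.shape[0]
    alpha = np.empty((T, R, t))
    c = np.empty((T, R))
    a = pi[None, :] * E[:, obs[:, 0]].T
    c[0] = a.sum(axis=1)
    if (c[0] == 0.0).any():
        raise ValueError("zero-probability run in E-step")
    alpha[0] = a / c[0][:, None]
    for tau in range(1, T):
        a = (alpha[tau - 1] @ A) * E[:, obs[:, tau]].T
        c[tau] = a.sum(axis=1)
        if (c[tau] == 0.0).any():
            raise ValueError("zero-probability run in E-step")
        alpha[tau] = a / c[tau][:, None]
    loglik = float(np.log(c).sum())

    beta = np.ones((R, t))
    gamma_sum = np.zeros((t,))
    emit_counts = np.zeros((t, E.shape[1]))
    xi_sum = np.zeros((t, t))
    # last time step gamma
    gamma = alpha[T - 1] * beta
    np.add.at(emit_counts.T, obs[:, T - 1], gamma)
    for tau in range(T - 2, -1, -1):
        eb = E[:, obs[:, tau + 1]].T * beta            # (R, t)
        xi = np.einsum("ri,ij,rj->ij", alpha[tau], A, eb / c[tau + 1][:, None])
        xi_sum += xi
        beta = (eb @ A.T) / c[tau + 1][:, None]
        gamma = alpha[tau] * beta
        np.add.at(emit_counts.T, obs[:, tau], gamma)
    gamma1_sum = (alpha[0] * beta).sum(axis=0) if T > 1 else alpha[0].sum(axis=0)
    del gamma_sum
    return loglik, gamma1_sum, xi_sum, emit_counts


def fit_hmm(close_runs: Iterable[Sequence[int]], t: int,
            fixed_E: np.ndarray | None = None, n_restarts: int = 3,
            max_iter: int = 200, tol: float = 1e-6, seed: int = 0,
            n_categories: int = N_CATEGORIES) -> HmmModel:
    """Estimate HMM parameters over a collection of close runs by
    Baum-Welch EM, maximizing the total log-likelihood across runs.

    If ``fixed_E`` is given (t x 96 reference signature profiles), only pi
    and A are re-estimated and the best of ``n_restarts`` random
    initializations is returned.  The per-iteration log-likelihood is
    non-decreasing; non-convergence within ``max_iter`` is flagged on the
    returned model, not an error.
    """
    runs = [np.asarray(r, dtype=int) for r in close_runs if len(r) > 0]
    if not runs:
        raise ValueError("need at least one nonempty close run")
    if t < 1:
        raise ValueError("t must be >= 1")
    all_obs = np.concatenate(runs)

    if fixed_E is not None:
        fixed_E = floor_emissions(np.asarray(fixed_E, dtype=float))
        if fixed_E.shape[0] != t:
            raise ValueError("fixed_E row count must equal t")
        if t > len(np.unique(all_obs)) and (fixed_E > 0.5).any():
            logger.warning("t exceeds the number of distinct observed categories "
                           "with near-degenerate fixed emissions")

    if t == 1:
        freq = np.bincount(all_obs, minlength=n_categories).astype(float)
        E = fixed_E if fixed_E is not None else (freq / freq.sum())[None, :]
        model = HmmModel(np.array([1.0]), np.array([[1.0]]), E,
                         emissions_fixed=fixed_E is not None)
        model.log_likelihood = sum(forward_logprob(model, r) for r in runs)
        return model

    # group runs by length for clean batched E-steps
    groups: dict[int, list[np.ndarray]] = {}
    for r in runs:
        groups.setdefault(len(r), []).append(r)
    batches = [np.stack(g) for g in groups.values()]

    rng = np.random.default_rng(seed)
    best: HmmModel | None = None
    for _ in range(max(1, n_restarts)):
        pi = rng.dirichlet(np.ones(t))
        A = rng.dirichlet(np.ones(t), size=t)
        if fixed_E is not None:
            E = fixed_E.copy()
        else:
            freq = np.bincount(all_obs, minlength=n_categories).astype(float) + 1.0
            E = rng.dirichlet(freq, size=t)
        prev_ll = -np.inf
        converged = False
        ll = prev_ll
        traj = []
        for _it in range(max_iter):
            ll = 0.0
            g1 = np.zeros(t)
            xi = np.zeros((t, t))
            emit = np.zeros((t, n_categories))
            for obs in batches:
                b_ll, b_g1, b_xi, b_emit = _batch_e_step(obs, pi, A, E)
                ll += b_ll
                g1 += b_g1
                xi += b_xi
                emit += b_emit
            traj.append(ll)
            pi = g1 / g1.sum()
            row = xi.sum(axis=1, keepdims=True)
            A = np.where(row > 0, xi / np.where(row > 0, row, 1.0), 1.0 / t)
            if fixed_E is None:
                erow = emit.sum(axis=1, keepdims=True)
                E = np.where(erow > 0, emit / np.where(erow > 0, erow, 1.0),
                             1.0 / n_categories)
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        model = HmmModel(pi, A, E, emissions_fixed=fixed_E is not None,
                         converged=converged, loglik_trajectory=traj)
        model.log_likelihood = float(prev_ll)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if not best.converged:
        logger.warning("fit_hmm: EM did not converge within %d iterations", max_iter)
    return best


# ---------------------------------------------------------------------------
# multinomial mixture
# ---------------------------------------------------------------------------

def mutation_count_vector(categories: Sequence[int],
                          n_categories: int = N_CATEGORIES) -> np.ndarray:
    """Count vector T over the 96 categories for the isolated mutations."""
    return np.bincount(np.asarray(categories, dtype=int), minlength=n_categories).astype(float)


def mmm_log_likelihood(model: MmmModel, counts: np.ndarray) -> float:
    mix = model.g @ model.E
    mix = np.maximum(mix, EMISSION_FLOOR)
    return float(counts @ np.log(mix))


def fit_mmm(isolated: Sequence[int], t: int, fixed_E: np.ndarray | None = None,
            max_iter: int = 500, tol: float = 1e-8, seed: int = 0,
            n_categories: int = N_CATEGORIES) -> MmmModel:
    """Estimate the multinomial mixture (g, E) over isolated mutations by EM
    on the category count vector T.

    With ``fixed_E`` only the mixing vector g is estimated, initialized by
    counting-based signature attribution of T (each category's counts
    credited to its highest-emission signature); otherwise both g and E are
    estimated from a seeded random start.  The log-likelihood is monotone.
    """
    cats = np.asarray(isolated, dtype=int)
    if cats.size == 0:
        raise ValueError("need at least one isolated mutation")
    if t < 1:
        raise ValueError("t must be >= 1")
    T = mutation_count_vector(cats, n_categories)
    total = T.sum()

    if fixed_E is not None:
        fixed_E = floor_emissions(np.asarray(fixed_E, dtype=float))
        if fixed_E.shape[0] != t:
            raise ValueError("fixed_E row count must equal t")

    if t == 1:
        E = fixed_E if fixed_E is not None else (T / total)[None, :]
        model = MmmModel(np.array([1.0]), E, emissions_fixed=fixed_E is not None)
        model.log_likelihood = mmm_log_likelihood(model, T)
        return model

    rng = np.random.default_rng(seed)
    if fixed_E is not None:
        E = fixed_E
        # counting-based initialization: attribute T to argmax-emission states
        attribution = np.argmax(E, axis=0)
        g = np.bincount(attribution, weights=T, minlength=t).astype(float)
        g = (g + 1.0) / (g.sum() + t)
    else:
        E = rng.dirichlet(T + 1.0, size=t)
        g = rng.dirichlet(np.ones(t))

    prev_ll = -np.inf
    converged = False
    traj = []
    for _ in range(max_iter):
        # responsibilities per category
        joint = g[:, None] * E                     # (t, 96)
        denom = np.maximum(joint.sum(axis=0), EMISSION_FLOOR)
        resp = joint / denom[None, :]
        weighted = resp * T[None, :]
        g = weighted.sum(axis=1) / total
        if fixed_E is None:
            rows = weighted.sum(axis=1, keepdims=True)
            E = np.where(rows > 0, weighted / np.where(rows > 0, rows, 1.0),
                         1.0 / n_categories)
        model = MmmModel(g, E, emissions_fixed=fixed_E is not None)
        ll = mmm_log_likelihood(model, T)
        traj.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    model = MmmModel(g, E, emissions_fixed=fixed_E is not None,
                     converged=converged, loglik_trajectory=traj)
    model.log_likelihood = float(prev_ll)
    if not converged:
        logger.warning("fit_mmm: EM did not converge within %d iterations", max_iter)
    return model


def decode_isolated(model: MmmModel, category: int) -> int:
    """Most probable component for one isolated mutation:
    argmax_j g[j] * E[j, category], ties toward the lower index."""
    if not 0 <= category < model.E.shape[1]:
        raise ValueError("category out of range")
    return int(np.argmax(model.g * model.E[:, category]))


# ---------------------------------------------------------------------------
# sequence probability and activities
# ---------------------------------------------------------------------------

def sequence_probability(partition: MutationPartition, hmm: HmmModel,
                         mmm: MmmModel) -> float:
    """Log probability of a sample's full mutation sequence: the product of
    the HMM likelihood of each close run and the mixture likelihood of each
    isolated mutation.  An empty partition has probability 1 (log 0.0)."""
    if hmm.t != mmm.t:
        raise ValueError("HMM and MMM must share the state count")
    logp = 0.0
    for run in partition.close_runs():
        logp += forward_logprob(hmm, run)
    iso = partition.isolated_categories()
    if iso.size:
        mix = np.maximum(mmm.g @ mmm.E[:, iso], EMISSION_FLOOR)
        logp += float(np.log(mix).sum())
    return logp


@dataclass
class SignatureActivity:
    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("activity counts must be nonnegative")


def signature_activity(partition: MutationPartition, hmm: HmmModel,
                       mmm: MmmModel) -> SignatureActivity:
    """Decode every mutation to a signature state (Viterbi per close run,
    posterior argmax per isolated mutation), reassemble in genomic order and
    count state occurrences.  Counts sum to the sample's mutation count."""
    if hmm.t != mmm.t:
        raise ValueError("HMM and MMM must share the state count")
    states: list[np.ndarray] = []
    for run in partition.runs:
        if run.kind == "close":
            states.append(viterbi(hmm, run.categories))
        else:
            states.append(np.array([decode_isolated(mmm, int(c))
                                    for c in run.categories], dtype=int))
    path = np.concatenate(states) if states else np.empty(0, dtype=int)
    counts = np.bincount(path, minlength=hmm.t)
    return SignatureActivity(partition.sample_id, counts)


def activity_matrix(partitions: dict[str, MutationPartition], hmm: HmmModel,
                    mmm: MmmModel, normalized: bool = False) -> pd.DataFrame:
    """Samples x signatures activity table (raw counts by default; per-sample
    fractions when ``normalized``)."""
    rows = {}
    for sample, part in partitions.items():
        act = signature_activity(part, hmm, mmm).counts.astype(float)
        if normalized and act.sum() > 0:
            act = act / act.sum()
        rows[sample] = act
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"sig{j}" for j in range(hmm.t)])
    return df.sort_index()


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def select_genes(expression: pd.DataFrame, activities: pd.DataFrame,
                 rho_threshold: float = 0.2,
                 use_abs: bool = False) -> tuple[list[str], pd.DataFrame]:
    """Select genes whose expression correlates (Spearman) with at least one
    signature activity across samples.

    ``expression`` is samples x genes, ``activities`` samples x signatures,
    aligned on the sample index.  A gene is selected iff its maximum rho
    (signed by default; absolute value with ``use_abs``) over signatures
    exceeds ``rho_threshold``.  Genes with constant expression have
    undefined correlation and are excluded (logged).  Returns the selected
    gene ids and the full (gene, signature, rho) table.
    """
    common = expression.index.intersection(activities.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned samples")
    X = expression.loc[common]
    Y = activities.loc[common]
    records = []
    selected = []
    xr = X.rank(axis=0).to_numpy()
    yr = Y.rank(axis=0).to_numpy()
    xr_std = xr.std(axis=0)
    yr_std = yr.std(axis=0)
    xr_c = xr - xr.mean(axis=0)
    yr_c = yr - yr.mean(axis=0)
    n = len(common)
    for gi, gene in enumerate(X.columns):
        if xr_std[gi] == 0:
            logger.info("select_genes: excluding constant gene %s", gene)
            continue
        rhos = np.full(Y.shape[1], np.nan)
        ok = yr_std > 0
        rhos[ok] = (xr_c[:, gi] @ yr_c[:, ok]) / (n * xr_std[gi] * yr_std[ok])
        for sj, sig in enumerate(Y.columns):
            records.append((gene, sig, rhos[sj]))
        score = np.nanmax(np.abs(rhos) if use_abs else rhos) if ok.any() else np.nan
        if np.isfinite(score) and score > rho_threshold:
            selected.append(gene)
    table = pd.DataFrame(records, columns=["gene", "signature", "rho"])
    return selected, table
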