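"""Synthetic pharmacogenomic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here: a MAF-like
substitution table whose close/isolated run structure, hidden signature
states and 96-category emissions are drawn from a known HMM/multinomial
mixture; and a GDSC/CCLE-shaped omics + response panel where IC50 is a
noisy low-rank factor model (U_true V_true^T + biases + noise), expression
"signal" genes track the latent cell-line factors, and drug fingerprints
carry shared substructure blocks so Jaccard similarity is informative.

These generators emulate the statistical structure the method assumes, not
the marginal distributions of real panels.  All of them are pure functions
of (parameters, seed), and every file they write round-trips bit-exactly
through :mod:`siglmf.io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .mutsig import N_CATEGORIES, category_context, _COMP

# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------


def _check_simplex(v: np.ndarray, name: str, axis: int | None = None) -> None:
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError(f"{name}: negative probabilities")
    sums = v.sum() if axis is None else v.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError(f"{name}: probabilities must sum to 1 (got {sums})")


@dataclass
class SignatureTruth:
    """Generating HMM/MMM parameters: start vector pi, transition matrix A,
    emission matrix E (t x 96) and mixing vector g, all row-stochastic."""

    pi: np.ndarray
    A: np.ndarray
    E: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        t = self.pi.shape[0]
        if self.A.shape != (t, t) or self.E.shape[0] != t or self.g.shape != (t,):
            raise ValueError("inconsistent truth dimensions")
        _check_simplex(self.pi, "pi")
        _check_simplex(self.g, "g")
        _check_simplex(self.A, "A", axis=1)
        _check_simplex(self.E, "E", axis=1)

    @property
    def t(self) -> int:
        return self.pi.shape[0]

    def marginal_mixture(self, close_frac: float,
                         mean_run_len: float = 4.0) -> np.ndarray:
        """Analytic marginal category distribution of a generated dataset.

        A close run of geometric length with mean ``mean_run_len`` starts
        from pi and evolves by A, so position k of a surviving run carries
        state mix pi A^(k-1) with weight (1-p)^(k-1) p; summing the series
        gives the close-mutation state marginal p * pi (I - (1-p) A)^-1.
        Isolated mutations draw states i.i.d. from g.
        """
        p = 1.0 / mean_run_len
        t = self.t
        close_state = p * (self.pi @ np.linalg.inv(np.eye(t) - (1.0 - p) * self.A))
        close_state = close_state / close_state.sum()
        close_marginal = close_state @ self.E
        iso_marginal = self.g @ self.E
        return close_frac * close_marginal + (1.0 - close_frac) * iso_marginal


def random_signature_truth(t: int, seed: int = 0,
                           emission_concentration: float = 0.1,
                           self_transition: float = 0.7) -> SignatureTruth:
    """A well-separated random truth: sparse Dirichlet emissions (real
    mutational signatures concentrate most mass on a handful of the 96
    categories), sticky transitions, non-degenerate pi and g."""
    rng = np.random.default_rng(seed)
    E = rng.dirichlet(np.full(N_CATEGORIES, emission_concentration), size=t)
    A = np.full((t, t), (1.0 - self_transition) / max(t - 1, 1))
    np.fill_diagonal(A, self_transition if t > 1 else 1.0)
    pi = rng.dirichlet(np.full(t, 5.0))
    g = rng.dirichlet(np.full(t, 5.0))
    return SignatureTruth(pi, A, E, g)


@dataclass
class PlantedResponseTruth:
    """Ground truth of the planted logistic/low-rank response model."""

    U_true: np.ndarray
    V_true: np.ndarray
    bias_c: np.ndarray
    bias_d: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.U_true = np.asarray(self.U_true, dtype=float)
        self.V_true = np.asarray(self.V_true, dtype=float)
        self.bias_c = np.asarray(self.bias_c, dtype=float)
        self.bias_d = np.asarray(self.bias_d, dtype=float)
        if self.U_true.shape[1] != self.V_true.shape[1] or self.U_true.shape[1] < 1:
            raise ValueError("latent dimension mismatch or L < 1")
        if not (np.isfinite(self.U_true).all() and np.isfinite(self.V_true).all()):
            raise ValueError("non-finite truth entries")

    @property
    def L(self) -> int:
        return self.U_true.shape[1]


def random_response_truth(n: int, m: int, L: int, noise_sd: float = 0.5,
                          seed: int = 0, factor_scale: float = 1.0) -> PlantedResponseTruth:
    rng = np.random.default_rng(seed)
    return PlantedResponseTruth(
        U_true=rng.normal(0.0, factor_scale, size=(n, L)),
        V_true=rng.normal(0.0, factor_scale, size=(m, L)),
        bias_c=rng.normal(0.0, 0.2, size=n),
        bias_d=rng.normal(0.0, 0.2, size=m),
        noise_sd=float(noise_sd),
    )


# ---------------------------------------------------------------------------
# mutation dataset
# ---------------------------------------------------------------------------

# within-close-run gaps are < 2000 bp; any other consecutive gap is > 2000 bp
# so re-splitting the table reproduces the planted runs exactly
_CLOSE_GAP = (1, 1999)
_FAR_GAP = (2001, 9999)


def gen_mutation_dataset(truth: SignatureTruth, n_samples: int,
                         mean_run_len: float = 4.0, close_frac: float = 0.5,
                         seed: int = 0, mean_mutations: float = 80.0,
                         ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate per-sample mutation tables from the planted HMM/MMM.

    Each sample is an alternation of close runs (states follow the HMM) and
    isolated stretches (states i.i.d. from g), starting with a close run.
    Close-run lengths are geometric with mean ``mean_run_len``; isolated
    stretch lengths are geometric with a mean chosen so that a fraction
    ``close_frac`` of mutations are close in expectation.  Positions sit on
    one pseudo-chromosome with within-run gaps < 2000 bp and all other gaps
    > 2000 bp.  Returns the MAF-like table (sample, chrom, pos, ref, alt,
    context5, context3) and each sample's true hidden-state path in genomic
    order.
    """
    if not 0.0 < close_frac < 1.0:
        raise ValueError("close_frac must be in (0, 1)")
    if mean_run_len < 1.0:
        raise ValueError("mean_run_len must be >= 1")
    rng = np.random.default_rng(seed)
    iso_mean = max(1.0, mean_run_len * (1.0 - close_frac) / close_frac)
    t = truth.t
    rows: list[tuple] = []
    paths: dict[str, np.ndarray] = {}
    width = len(str(max(n_samples - 1, 1)))
    for s in range(n_samples):
        sample = f"S{s:0{width}d}"
        n_mut = max(2, int(rng.poisson(mean_mutations)))
        states: list[int] = []
        kinds: list[bool] = []          # True = close
        close_turn = True               # first run of a sample is close
        while len(states) < n_mut:
            if close_turn:
                run_len = int(rng.geometric(1.0 / mean_run_len))
                run_len = min(run_len, n_mut - len(states))
                state = int(rng.choice(t, p=truth.pi))
                for i in range(run_len):
                    if i > 0:
                        state = int(rng.choice(t, p=truth.A[state]))
                    states.append(state)
                    kinds.append(True)
            else:
                run_len = int(rng.geometric(1.0 / iso_mean))
                run_len = min(run_len, n_mut - len(states))
                for _ in range(run_len):
                    states.append(int(rng.choice(t, p=truth.g)))
                    kinds.append(False)
            close_turn = not close_turn
        pos = 10_000
        path = np.array(states, dtype=int)
        for i, (state, is_close) in enumerate(zip(states, kinds)):
            if i > 0:
                # the split rule looks backward: a mutation is close iff the
                # gap to its predecessor is small, so a close run opening
                # after an isolated stretch still gets a small leading gap
                lo, hi = _CLOSE_GAP if is_close else _FAR_GAP
                pos += int(rng.integers(lo, hi + 1))
            cat = int(rng.choice(N_CATEGORIES, p=truth.E[state]))
            ref, alt, five, three = category_context(cat)
            if rng.random() < 0.5:  # report on the purine strand
                ref, alt = _COMP[ref], _COMP[alt]
                five, three = _COMP[three], _COMP[five]
            rows.append((sample, "1", pos, ref, alt, five, three))
        paths[sample] = path
    maf = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                      "context5", "context3"])
    return maf, paths


def true_activity_matrix(paths: dict[str, np.ndarray], t: int) -> pd.DataFrame:
    """Per-sample true signature activities (state occurrence counts)."""
    rows = {s: np.bincount(p, minlength=t) for s, p in paths.items()}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"sig{j}" for j in range(t)]).sort_index()


def gen_signature_expression(activities: pd.DataFrame, n_genes: int,
                             n_signal_genes: int, noise_sd: float = 0.5,
                             seed: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """Expression panel where ``n_signal_genes`` genes track one signature
    activity each (standardized activity + Gaussian noise) and the rest are
    pure noise.  Returns (samples x genes table, planted signal gene ids)."""
    if n_signal_genes > n_genes:
        raise ValueError("n_signal_genes must be <= n_genes")
    rng = np.random.default_rng(seed)
    n, t = activities.shape
    act = activities.to_numpy(dtype=float)
    act = (act - act.mean(axis=0)) / np.maximum(act.std(axis=0), 1e-9)
    X = rng.normal(size=(n, n_genes))
    signal_idx = rng.choice(n_genes, size=n_signal_genes, replace=False)
    for j, gi in enumerate(signal_idx):
        X[:, gi] = act[:, j % t] + noise_sd * rng.normal(size=n)
    genes = [f"G{j:04d}" for j in range(n_genes)]
    df = pd.DataFrame(X, index=activities.index, columns=genes)
    return df, [genes[gi] for gi in sorted(signal_idx)]


# ---------------------------------------------------------------------------
# omics + response panel
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    """A full synthetic pharmacogenomic panel plus its planted truth."""

    expression: pd.DataFrame        # n x n_genes, fully observed
    cnv: pd.DataFrame               # n x n_cnv, NaN = missing
    mutation: pd.DataFrame          # n x n_genes binary, NaN = missing
    ic50: pd.DataFrame              # n x m, NaN = missing
    tissue: pd.Series               # n labels
    fingerprints: pd.DataFrame      # m x 881 bits
    maf: pd.DataFrame | None = None
    truth: PlantedResponseTruth | None = None
    signature_truth: SignatureTruth | None = None
    true_paths: dict[str, np.ndarray] = field(default_factory=dict)
    signal_genes: list[str] = field(default_factory=list)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.ic50.columns)


N_FINGERPRINT_BITS = 881


def gen_omics_response_dataset(n: int, m: int, truth: PlantedResponseTruth,
                               n_genes: int = 100, n_signal_genes: int = 30,
                               tissues: int = 4, missing_frac: float = 0.1,
                               seed: int = 0, n_cnv_features: int = 60,
                               n_cnv_signal: int = 15,
                               signal_noise_sd: float = 0.3) -> SyntheticPanel:
    """GDSC/CCLE-shaped synthetic panel around a planted factor model.

    IC50 = U_true V_true^T + biases + N(0, noise_sd); signal genes in the
    expression and CNV tables are noisy reads of the latent cell-line
    factors, mutation probabilities follow a logistic link of one factor
    each, and tissue labels bin the first latent factor (so every
    similarity layer carries information about latent proximity).  A
    fraction ``missing_frac`` of CNV, mutation and IC50 entries is masked.
    """
    if not 0.0 <= missing_frac < 0.5:
        raise ValueError("missing_frac must be in [0, 0.5): higher would trip "
                         "the half-missing removal rule everywhere")
    if n_signal_genes > n_genes or n_cnv_signal > n_cnv_features:
        raise ValueError("signal feature count exceeds total features")
    if truth.U_true.shape[0] != n or truth.V_true.shape[0] != m:
        raise ValueError("truth dimensions do not match n, m")
    rng = np.random.default_rng(seed)
    L = truth.L
    U, V = truth.U_true, truth.V_true

    cells = [f"CL{i:03d}" for i in range(n)]
    drugs = [f"D{j:02d}" for j in range(m)]
    genes = [f"G{j:04d}" for j in range(n_genes)]
    cnv_ids = [f"C{j:04d}" for j in range(n_cnv_features)]

    ic50 = U @ V.T + truth.bias_c[:, None] + truth.bias_d[None, :]
    if truth.noise_sd > 0:
        ic50 = ic50 + rng.normal(0.0, truth.noise_sd, size=(n, m))

    expr = rng.normal(size=(n, n_genes))
    for j in range(n_signal_genes):
        expr[:, j] = U[:, j % L] + signal_noise_sd * rng.normal(size=n)
    # interleave signal genes through the panel deterministically
    perm = rng.permutation(n_genes)          # old column j lands at perm[j]
    expr = expr[:, np.argsort(perm)]
    signal_genes = sorted(genes[perm[j]] for j in range(n_signal_genes))

    cnv = rng.normal(size=(n, n_cnv_features))
    for j in range(n_cnv_signal):
        cnv[:, j] = U[:, (j + 1) % L] + signal_noise_sd * rng.normal(size=n)

    logits = np.empty((n, n_genes))
    for j in range(n_genes):
        logits[:, j] = 1.5 * U[:, j % L] - 2.0
    mut = (rng.random((n, n_genes)) < 1.0 / (1.0 + np.exp(-logits))).astype(float)

    # tissue = quantile bin of the first latent factor
    order = np.argsort(np.argsort(U[:, 0]))
    tissue = pd.Series([f"T{int(r * tissues / n)}" for r in order],
                       index=cells, name="tissue")

    fp = (rng.random((m, N_FINGERPRINT_BITS)) < 0.15).astype(int)
    # shared substructure blocks among consecutive drug pairs
    block = 40
    for grp in range(m // 2):
        pattern = (rng.random(block) < 0.5).astype(int)
        lo = (grp * block) % (N_FINGERPRINT_BITS - block)
        fp[2 * grp, lo:lo + block] = pattern
        fp[2 * grp + 1, lo:lo + block] = pattern

    cnv_df = pd.DataFrame(cnv, index=cells, columns=cnv_ids)
    mut_df = pd.DataFrame(mut, index=cells, columns=genes)
    ic50_df = pd.DataFrame(ic50, index=cells, columns=drugs)
    if missing_frac > 0:
        for df in (cnv_df, mut_df, ic50_df):
            mask = rng.random(df.shape) < missing_frac
            df.mask(mask, inplace=True)

    return SyntheticPanel(
        expression=pd.DataFrame(expr, index=cells, columns=genes),
        cnv=cnv_df, mutation=mut_df, ic50=ic50_df, tissue=tissue,
        fingerprints=pd.DataFrame(fp, index=drugs,
                                  columns=[f"FP{b:03d}" for b in range(N_FINGERPRINT_BITS)]),
        truth=truth, signal_genes=signal_genes,
    )


def attach_mutation_data(panel: SyntheticPanel, sig_truth: SignatureTruth,
                         mean_run_len: float = 4.0, close_frac: float = 0.5,
                         mean_mutations: float = 80.0, seed: int = 0) -> SyntheticPanel:
    """Add a planted-signature MAF to an omics panel, one mutation sequence
    per cell line (sample ids match cell ids)."""
    maf, paths = gen_mutation_dataset(sig_truth, len(panel.cell_ids),
                                      mean_run_len, close_frac, seed,
                                      mean_mutations)
    ids = panel.cell_ids
    rename = {s: ids[i] for i, s in enumerate(sorted(set(maf["sample"])))}
    maf = maf.assign(sample=maf["sample"].map(rename))
    panel.maf = maf
    panel.signature_truth = sig_truth
    panel.true_paths = {rename[s]: p for s, p in paths.items()}
    return panel


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_panel(panel: SyntheticPanel, outdir: str | Path) -> None:
    """Write every table in the pipeline's TSV dialect plus JSON ground-truth
    sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_matrix_tsv(panel.expression, outdir / "expression.tsv")
    sio.write_matrix_tsv(panel.cnv, outdir / "cnv.tsv")
    sio.write_matrix_tsv(panel.mutation, outdir / "mutation.tsv")
    sio.write_matrix_tsv(panel.ic50, outdir / "ic50.tsv")
    sio.write_matrix_tsv(panel.tissue.to_frame(), outdir / "tissue.tsv")
    sio.write_matrix_tsv(panel.fingerprints, outdir / "fingerprints.tsv")
    if panel.maf is not None:
        sio.write_table_tsv(panel.maf, outdir / "mutations_maf.tsv")
    sidecar: dict = {}
    if panel.truth is not None:
        tr = panel.truth
        sidecar["response_truth"] = {
            "U_true": tr.U_true.tolist(), "V_true": tr.V_true.tolist(),
            "bias_c": tr.bias_c.tolist(), "bias_d": tr.bias_d.tolist(),
            "noise_sd": tr.noise_sd,
        }
    if panel.signature_truth is not None:
        st = panel.signature_truth
        sidecar["signature_truth"] = {"pi": st.pi.tolist(), "A": st.A.tolist(),
                                      "E": st.E.tolist(), "g": st.g.tolist()}
    if panel.true_paths:
        sidecar["true_paths"] = {s: p.tolist() for s, p in panel.true_paths.items()}
    if panel.signal_genes:
        sidecar["signal_genes"] = panel.signal_genes
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_panel(indir: str | Path) -> SyntheticPanel:
    indir = Path(indir)
    tissue_df = sio.read_matrix_tsv(indir / "tissue.tsv")
    panel = SyntheticPanel(
        expression=sio.read_matrix_tsv(indir / "expression.tsv"),
        cnv=sio.read_matrix_tsv(indir / "cnv.tsv"),
        mutation=sio.read_matrix_tsv(indir / "mutation.tsv"),
        ic50=sio.read_matrix_tsv(indir / "ic50.tsv"),
        tissue=tissue_df["tissue"],
        fingerprints=sio.read_matrix_tsv(indir / "fingerprints.tsv"),
    )
    maf_path = indir / "mutations_maf.tsv"
    if maf_path.exists():
        panel.maf = sio.read_table_tsv(maf_path).astype({"sample": str,
                                                         "chrom": str})
    gt_path = indir / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            sidecar = json.load(fh)
        if "response_truth" in sidecar:
            rt = sidecar["response_truth"]
            panel.truth = PlantedResponseTruth(
                np.array(rt["U_true"]), np.array(rt["V_true"]),
                np.array(rt["bias_c"]), np.array(rt["bias_d"]), rt["noise_sd"])
        if "signature_truth" in sidecar:
            st = sidecar["signature_truth"]
            panel.signature_truth = SignatureTruth(
                np.array(st["pi"]), np.array(st["A"]),
                np.array(st["E"]), np.array(st["g"]))
        panel.true_paths = {s: np.array(p, dtype=int)
                            for s, p in sidecar.get("true_paths", {}).items()}
        panel.signal_genes = sidecar.get("signal_genes", [])
    return panel
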