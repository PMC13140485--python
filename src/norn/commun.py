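"""Distance-constrained ligand-receptor communication scoring.

Sender spots are the non-receiver spots lying within a diffusion radius
(default 250 µm) of at least one Epo+ receiver spot, grouped by their
deconvolution-dominant cell type. For an interaction with (possibly
multi-subunit) ligand L and receptor R, the communication probability is a
product of Hill functions of the sender-side ligand level and the
receiver-side receptor level; subunit levels combine by geometric mean so
that every subunit of a heterodimeric complex is required. Significance is
a one-sided permutation test that reshuffles spot labels between the sender
group and the receivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class Interaction:
    """One ligand-receptor record; subunit lists encode complexes."""

    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    pathway: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError("an interaction needs >=1 ligand and >=1 receptor subunit")

    @property
    def name(self) -> str:
        return "+".join(self.ligand_subunits) + "->" + "+".join(self.receptor_subunits)


def demo_lr_database() -> list[Interaction]:
    """Small built-in interaction set for the simulated kidney panel."""
    return [
        Interaction(("Spp1",), ("Cd44",), "SPP1"),
        Interaction(("Spp1",), ("Itgav", "Itgb3"), "SPP1"),
        Interaction(("Tgfb1",), ("Tgfbr1", "Tgfbr2"), "TGFb"),
    ]


def normalized_expression(counts) -> pd.DataFrame:
    """Depth-normalized expression on a log scale: log1p(counts per 10k).

    This is the expression layer the communication score consumes; typical
    values are O(1), matching the default half-saturation constant."""
    from norn.spots import _dense_counts

    X, spot_idx, gene_idx = _dense_counts(counts)
    depth = X.sum(axis=1, keepdims=True)
    if np.any(depth <= 0):
        raise ValueError("every spot must have positive depth")
    return pd.DataFrame(np.log1p(X / depth * 1e4), index=spot_idx, columns=gene_idx)


def define_senders(
    dominant: pd.Series,
    positions: np.ndarray,
    receivers: np.ndarray,
    radius_um: float = 250.0,
    min_group_size: int = 10,
) -> dict[str, np.ndarray]:
    """Group candidate sender spots by dominant cell type.

    A sender is a non-receiver spot whose centre lies within ``radius_um``
    of at least one receiver centre (inclusive). Groups smaller than
    ``min_group_size`` are dropped with a log entry. Returns a mapping of
    cell type -> integer spot indices.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    receivers = np.asarray(receivers, dtype=bool)
    positions = np.asarray(positions, dtype=float)
    if receivers.sum() == 0:
        raise ValueError("no receiver spots")
    tree = cKDTree(positions[receivers])
    d, _ = tree.query(positions, k=1)
    in_range = (d <= radius_um) & ~receivers
    idx = np.flatnonzero(in_range)
    labels = np.asarray(dominant)[idx]
    groups: dict[str, np.ndarray] = {}
    for ctype in pd.unique(labels):
        members = idx[labels == ctype]
        if len(members) < min_group_size:
            logger.info("sender group %r dropped (%d < %d spots)", ctype, len(members), min_group_size)
            continue
        groups[str(ctype)] = members
    return groups


def _subunit_level(expr: pd.DataFrame, spots: np.ndarray, subunits: tuple[str, ...]) -> float:
    """Geometric mean over subunits of the mean expression in a spot set;
    0 if any subunit gene is absent (complex cannot form)."""
    means = []
    for gene in subunits:
        if gene not in expr.columns:
            logger.info("subunit %r absent from expression matrix", gene)
            return 0.0
        means.append(float(expr[gene].to_numpy()[spots].mean()))
    means = np.asarray(means)
    if np.any(means <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(means))))


def _hill(x: float, K: float, n: float) -> float:
    if x <= 0:
        return 0.0
    return x**n / (K**n + x**n)


def communication_probability(
    expr: pd.DataFrame,
    senders: np.ndarray,
    receivers: np.ndarray,
    interaction: Interaction,
    K: float = 0.5,
    n: float = 1.0,
    mode: str = "hill",
) -> float:
    """Bounded ligand-receptor signalling score between one sender group
    and the receivers.

    P = Hill(L) * Hill(R) with L the sender-side ligand level and R the
    receiver-side receptor level (geometric means over subunits);
    mode="mass_action" uses P = L*R / (1 + L*R) instead. P is in [0, 1]
    and is 0 whenever a required subunit is absent or silent.
    """
    senders = np.asarray(senders)
    if senders.size == 0:
        raise ValueError("empty sender group")
    receivers_idx = np.flatnonzero(receivers) if np.asarray(receivers).dtype == bool else np.asarray(receivers)
    L = _subunit_level(expr, senders, interaction.ligand_subunits)
    R = _subunit_level(expr, receivers_idx, interaction.receptor_subunits)
    if mode == "hill":
        return _hill(L, K, n) * _hill(R, K, n)
    if mode == "mass_action":
        return L * R / (1.0 + L * R)
    raise ValueError(f"unknown mode {mode!r}")


def permutation_test(
    expr: pd.DataFrame,
    senders: np.ndarray,
    receivers: np.ndarray,
    interaction: Interaction,
    B: int = 1000,
    seed: int = 0,
    K: float = 0.5,
    n: float = 1.0,
    mode: str = "hill",
) -> tuple[float, float]:
    """One-sided permutation p-value for a communication probability.

    The pooled sender + receiver spot set is relabelled B times preserving
    group sizes; p = (1 + #{P_perm >= P_obs}) / (1 + B) (add-one corrected,
    so p is never 0). Degenerate (all-zero) expression of the interaction
    genes yields p = 1. Returns (P_obs, p).
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    senders = np.asarray(senders)
    receivers_idx = np.flatnonzero(receivers) if np.asarray(receivers).dtype == bool else np.asarray(receivers)
    p_obs = communication_probability(expr, senders, receivers_idx, interaction, K=K, n=n, mode=mode)

    genes = tuple(interaction.ligand_subunits) + tuple(interaction.receptor_subunits)
    if any(g not in expr.columns for g in genes):
        return p_obs, 1.0
    pool = np.concatenate([senders, receivers_idx])
    vals = expr.loc[:, list(genes)].to_numpy()[pool]  # (n_pool, n_genes)
    if not np.any(vals > 0):
        return p_obs, 1.0

    ns = len(senders)
    nl, nr = len(interaction.ligand_subunits), len(interaction.receptor_subunits)
    rng = np.random.default_rng(seed)
    count = 0
    # vectorized label shuffles: each row of `order` is one permutation
    order = np.argsort(rng.random((B, len(pool))), axis=1)
    perm_vals = vals[order]  # (B, n_pool, n_genes)
    s_means = perm_vals[:, :ns, :].mean(axis=1)
    r_means = perm_vals[:, ns:, :].mean(axis=1)

    def geo(m: np.ndarray) -> np.ndarray:
        out = np.zeros(len(m))
        ok = np.all(m > 0, axis=1)
        out[ok] = np.exp(np.mean(np.log(m[ok]), axis=1))
        return out

    L = geo(s_means[:, :nl])
    R = geo(r_means[:, nl:])
    if mode == "hill":
        p_perm = (L**n / (K**n + L**n)) * (R**n / (K**n + R**n))
        p_perm[L <= 0] = 0.0
        p_perm[R <= 0] = 0.0
    else:
        p_perm = L * R / (1.0 + L * R)
    count = int(np.sum(p_perm >= p_obs))
    return p_obs, (1 + count) / (1 + B)


@dataclass
class CommResult:
    """Long table of per (sender type, interaction) scores and p-values."""

    table: pd.DataFrame  # sender, interaction, pathway, probability, p, n_senders
    condition: str = ""
    n_permutations: int = 0


def score_communication(
    expr: pd.DataFrame,
    sender_groups: dict[str, np.ndarray],
    receivers: np.ndarray,
    interactions: list[Interaction],
    B: int = 1000,
    seed: int = 0,
    condition: str = "",
    K: float = 0.5,
    n: float = 1.0,
    mode: str = "hill",
) -> CommResult:
    """Score every (sender group, interaction) pair with permutation p."""
    rows = []
    for g, (ctype, spots) in enumerate(sorted(sender_groups.items())):
        for i, inter in enumerate(interactions):
            prob, p = permutation_test(
                expr, spots, receivers, inter, B=B,
                seed=np.random.SeedSequence([seed, g, i]).generate_state(1)[0] % (2**31),
                K=K, n=n, mode=mode,
            )
            rows.append(
                {
                    "sender": ctype,
                    "interaction": inter.name,
                    "pathway": inter.pathway,
                    "probability": prob,
                    "p": p,
                    "n_senders": len(spots),
                }
            )
    return CommResult(table=pd.DataFrame(rows), condition=condition, n_permutations=B)


def condition_compare(
    results_a: CommResult, results_b: CommResult, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag pairs significant in exactly one condition.

    Conditions must cover the same (sender, interaction) pairs; a mismatch
    is an error listing the difference. Output is a dot-plot-ready long
    table with probability and p per condition and a flag in
    {A_only, B_only, both, neither} at p < alpha.
    """
    a = results_a.table.set_index(["sender", "interaction"])
    b = results_b.table.set_index(["sender", "interaction"])
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"interaction sets differ; only in A: {list(only_a)}, only in B: {list(only_b)}"
        )
    merged = a[["pathway", "probability", "p"]].join(
        b[["probability", "p"]], lsuffix="_a", rsuffix="_b"
    )
    sig_a = merged["p_a"] < alpha
    sig_b = merged["p_b"] < alpha
    merged["flag"] = np.select(
        [sig_a & sig_b, sig_a & ~sig_b, ~sig_a & sig_b],
        ["both", "A_only", "B_only"],
        default="neither",
    )
    merged["condition_a"] = results_a.condition
    merged["condition_b"] = results_b.condition
    return merged.reset_index()
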