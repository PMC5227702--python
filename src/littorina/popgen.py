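"""Haplotype-level population genetics for aligned mtDNA (COI) sequences.

Covers the sequence side of the regional-adaptation analysis: haplotype
collapse and diversity statistics, uncorrected p-distances, base-composition
homogeneity, hierarchical AMOVA with the three Phi fixation indices and their
permutation nulls, net divergence (D_a) between populations, a neighbour
joining population tree, and a minimum-spanning haplotype network.

Distance conventions
--------------------
AMOVA uses the absolute number of pairwise nucleotide differences (the
standard choice for haplotypic data); p-distance (the per-site proportion of
differences) is used for divergence summaries and D_a.  Sites where either
sequence carries an ambiguous state (N or a gap) are excluded pairwise, not
listwise.

Permutation schemes
-------------------
Phi_ST permutes individuals among populations; Phi_SC permutes individuals
among populations within their group; Phi_CT permutes whole populations among
groups.  p = fraction of permuted statistics >= observed (upper tail).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix
from skbio.tree import nj

logger = logging.getLogger(__name__)

VALID_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_PERMUTATIONS = 10_000


class InputError(ValueError):
    """Malformed sequence input or label mapping."""


# ---------------------------------------------------------------------------
# dataset container and IO
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeDataset:
    """Aligned sequences with population and group (climatic region) labels."""

    sequences: list[str]
    sample_ids: list[str]
    populations: list[str]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InputError(f"ragged alignment: lengths {sorted(lengths)}")
        if not (len(self.sequences) == len(self.sample_ids) == len(self.populations)):
            raise InputError("sequences/sample_ids/populations length mismatch")
        if self.groups is not None and len(self.groups) != len(self.sequences):
            raise InputError("groups length mismatch")
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_length(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """Sequences as a (n, L) uint8 byte matrix."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(len(self), self.seq_length)

    def subset(self, idx: np.ndarray) -> "HaplotypeDataset":
        return HaplotypeDataset(
            sequences=[self.sequences[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            groups=None if self.groups is None else [self.groups[i] for i in idx],
        )

    def to_fasta(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            for sid, seq in zip(self.sample_ids, self.sequences):
                handle.write(f">{sid}\n{seq}\n")
        finally:
            if close:
                handle.close()

    def mapping_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample": self.sample_ids, "population": self.populations})
        if self.groups is not None:
            out["group"] = self.groups
        return out


def read_fasta_with_labels(fasta, mapping: pd.DataFrame) -> HaplotypeDataset:
    """Load an aligned FASTA plus a (sample, population[, group]) table.

    Every FASTA record must appear in the mapping; mixed-case sequences are
    uppercased (logged).  Ragged alignments are rejected.
    """
    records = list(SeqIO.parse(fasta, "fasta"))
    if not records:
        raise InputError("empty FASTA")
    mapping = mapping.set_index("sample")
    seqs, ids, pops, groups = [], [], [], []
    has_groups = "group" in mapping.columns
    for rec in records:
        if rec.id not in mapping.index:
            raise InputError(f"record '{rec.id}' missing from mapping table")
        seq = str(rec.seq)
        if not seq.isupper():
            logger.info("uppercasing mixed-case record %s", rec.id)
        seqs.append(seq)
        ids.append(rec.id)
        pops.append(str(mapping.loc[rec.id, "population"]))
        if has_groups:
            groups.append(str(mapping.loc[rec.id, "group"]))
    return HaplotypeDataset(
        sequences=seqs,
        sample_ids=ids,
        populations=pops,
        groups=groups if has_groups else None,
    )


def fetch_genbank_sequences(
    accessions: list[str], email: str = "user@example.org", timeout: float = 15.0
) -> list:
    """Fetch nucleotide records from GenBank via NCBI E-utilities.

    Requires network access; raises ``URLError`` when NCBI is unreachable.
    Returns Biopython SeqRecords.
    """
    import socket
    from Bio import Entrez

    Entrez.email = email
    Entrez.max_tries = 1
    old = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        with Entrez.efetch(
            db="nucleotide", id=",".join(accessions), rettype="fasta", retmode="text"
        ) as handle:
            return list(SeqIO.parse(handle, "fasta"))
    finally:
        socket.setdefaulttimeout(old)


def accession_range(first: str, last: str) -> list[str]:
    """Expand an accession range like KP221321..KP221558 (same prefix)."""
    prefix = first.rstrip("0123456789")
    if last.rstrip("0123456789") != prefix:
        raise InputError("accession prefixes differ")
    lo, hi = int(first[len(prefix):]), int(last[len(prefix):])
    width = len(first) - len(prefix)
    return [f"{prefix}{i:0{width}d}" for i in range(lo, hi + 1)]


def trim_to_common_region(sequences: list[str]) -> list[str]:
    """Keep the longest contiguous block of columns free of gaps and Ns.

    For equal-length downloads of the same amplicon this recovers the common
    sequenced region shared by all records.
    """
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise InputError("sequences must be aligned (equal length) before trimming")
    enc = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype=np.uint8)
    enc = enc.reshape(len(sequences), -1)
    clean = np.all(np.isin(enc, VALID_BASES), axis=0)
    # longest run of True
    best_start = best_len = cur_start = cur_len = 0
    for j, ok in enumerate(clean):
        if ok:
            if cur_len == 0:
                cur_start = j
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    if best_len == 0:
        raise InputError("no clean common region")
    return [s.upper()[best_start : best_start + best_len] for s in sequences]


# ---------------------------------------------------------------------------
# haplotypes and diversity
# ---------------------------------------------------------------------------


def collapse_haplotypes(ds: HaplotypeDataset) -> pd.DataFrame:
    """Merge identical sequences into haplotypes.

    Returns a table with columns (haplotype, sequence, count, populations,
    private); haplotypes are numbered by decreasing frequency (ties by first
    occurrence).  A haplotype is private iff all its carriers come from a
    single population.
    """
    if len(ds) == 0:
        raise InputError("empty dataset")
    order: dict[str, list[int]] = {}
    for i, seq in enumerate(ds.sequences):
        order.setdefault(seq, []).append(i)
    items = sorted(order.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    rows = []
    for h, (seq, idx) in enumerate(items, start=1):
        pops = sorted({ds.populations[i] for i in idx})
        rows.append(
            {
                "haplotype": f"H{h}",
                "sequence": seq,
                "count": len(idx),
                "populations": ",".join(pops),
                "private": len(pops) == 1,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DiversitySummary:
    n: int
    n_hap: int
    n_ps: int
    mean_pairwise_diff: float
    h_e: float
    pi: float


def _pair_stats(enc: np.ndarray) -> tuple[float, float]:
    """Mean pairwise (absolute differences, p-distance) with pairwise deletion."""
    n = enc.shape[0]
    valid = np.isin(enc, VALID_BASES)
    total_diff = 0.0
    total_p = 0.0
    pairs = 0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & both
        comparable = both.sum(axis=1)
        if np.any(comparable == 0):
            raise InputError("a sequence pair has no comparable sites")
        d = diff.sum(axis=1)
        total_diff += d.sum()
        total_p += (d / comparable).sum()
        pairs += d.size
    return total_diff / pairs, total_p / pairs


def polymorphic_site_count(enc: np.ndarray) -> int:
    """Sites with >= 2 observed unambiguous states."""
    n_states = np.zeros(enc.shape[1], dtype=int)
    for b in VALID_BASES:
        n_states += np.any(enc == b, axis=0)
    return int(np.sum(n_states >= 2))


def diversity(ds: HaplotypeDataset, by_population: bool = True) -> dict[str, DiversitySummary]:
    """Haplotype and nucleotide diversity, overall and per population.

    H_e = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies; pi is the mean
    pairwise per-site proportion of differences (pairwise deletion); N_ps
    counts sites with at least two observed unambiguous states.
    """

    def one(sub: HaplotypeDataset) -> DiversitySummary:
        n = len(sub)
        if n < 2:
            raise InputError("diversity undefined for a single sequence")
        counts = np.array([len(v) for v in _hap_index(sub).values()])
        freqs = counts / n
        h_e = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
        enc = sub.encoded()
        mean_diff, pi = _pair_stats(enc)
        return DiversitySummary(
            n=n,
            n_hap=len(counts),
            n_ps=polymorphic_site_count(enc),
            mean_pairwise_diff=mean_diff,
            h_e=h_e,
            pi=pi,
        )

    out = {"overall": one(ds)}
    if by_population:
        pops = np.asarray(ds.populations)
        for pop in dict.fromkeys(ds.populations):
            out[pop] = one(ds.subset(np.flatnonzero(pops == pop)))
    return out


def _hap_index(ds: HaplotypeDataset) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i, s in enumerate(ds.sequences):
        idx.setdefault(s, []).append(i)
    return idx


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def difference_matrix(sequences: list[str]) -> np.ndarray:
    """Pairwise absolute nucleotide-difference counts (pairwise deletion)."""
    enc = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype=np.uint8)
    enc = enc.reshape(len(sequences), -1)
    valid = np.isin(enc, VALID_BASES)
    n = enc.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        d = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


def p_distance_matrix(sequences: list[str]) -> np.ndarray:
    """Uncorrected p-distance: proportion of differing sites over sites where
    both sequences have unambiguous bases."""
    enc = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype=np.uint8)
    enc = enc.reshape(len(sequences), -1)
    valid = np.isin(enc, VALID_BASES)
    n = enc.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        comparable = both.sum(axis=1)
        if np.any(comparable == 0):
            raise InputError("a sequence pair has no comparable sites")
        d = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1) / comparable
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


def base_composition(ds: HaplotypeDataset) -> dict[str, float]:
    """Overall percent composition of A, C, G, T over unambiguous sites."""
    enc = ds.encoded()
    counts = {chr(b): int(np.sum(enc == b)) for b in VALID_BASES}
    total = sum(counts.values())
    return {k: 100.0 * v / total for k, v in counts.items()}


def base_composition_homogeneity(
    ds: HaplotypeDataset,
    site_class: str = "all",
    codon_frame: int | None = None,
) -> tuple[float, int, float]:
    """Chi-square test of base-frequency homogeneity among sequences.

    ``site_class``: 'all', 'polymorphic', or 'third-codon' (requires
    ``codon_frame`` in {0,1,2}: the offset of the first codon's first base).
    Returns (chi2, df, p).
    """
    enc = ds.encoded()
    if site_class == "all":
        cols = np.ones(enc.shape[1], dtype=bool)
    elif site_class == "polymorphic":
        n_states = np.zeros(enc.shape[1], dtype=int)
        for b in VALID_BASES:
            n_states += np.any(enc == b, axis=0)
        cols = n_states >= 2
    elif site_class == "third-codon":
        if codon_frame is None:
            raise InputError("third-codon site class requires codon_frame")
        cols = np.zeros(enc.shape[1], dtype=bool)
        cols[codon_frame + 2 :: 3] = True
    else:
        raise InputError(f"unknown site class '{site_class}'")
    if not cols.any():
        raise InputError("empty site class")
    sub = enc[:, cols]
    table = np.stack([np.sum(sub == b, axis=1) for b in VALID_BASES], axis=1)
    nonzero_cols = table.sum(axis=0) > 0
    table = table[:, nonzero_cols]
    if table.shape[1] < 2 or np.all(table == table[0]):
        df = (table.shape[0] - 1) * max(table.shape[1] - 1, 0)
        return 0.0, df, 1.0
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_phi_st: float | None = None
    p_phi_sc: float | None = None
    p_phi_ct: float | None = None
    n_permutations: int = 0
    degenerate: bool = False


def _ssd(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for one cluster: (1/n) * sum_{i<j} d_ij."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _variance_components(
    d: np.ndarray, pops: np.ndarray, groups: np.ndarray | None
) -> tuple[float, float, float]:
    """Excoffier-style decomposition of squared pairwise distances.

    ``d`` holds the squared distances between individuals (for haplotype data
    the pairwise difference count itself).  Returns (sigma_a, sigma_b,
    sigma_c); for a two-level design sigma_a is 0 and sigma_b is the
    among-population component.
    """
    n_total = len(pops)
    all_idx = np.arange(n_total)
    ssd_total = _ssd(d, all_idx)

    pop_labels, pop_codes = np.unique(pops, return_inverse=True)
    n_pops = len(pop_labels)
    pop_sizes = np.bincount(pop_codes)
    ssd_wp = sum(_ssd(d, np.flatnonzero(pop_codes == p)) for p in range(n_pops))

    if groups is None:
        df_ap = n_pops - 1
        df_wp = n_total - n_pops
        sigma_c = (ssd_wp / df_wp) if df_wp > 0 else 0.0
        ms_ap = (ssd_total - ssd_wp) / df_ap
        n_prime = (n_total - np.sum(pop_sizes**2) / n_total) / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime
        return 0.0, float(sigma_b), float(sigma_c)

    grp_labels, grp_codes = np.unique(groups, return_inverse=True)
    n_groups = len(grp_labels)
    if n_groups < 2:
        raise InputError("hierarchical AMOVA needs >= 2 groups")
    grp_of_pop = {}
    for p, g in zip(pop_codes, grp_codes):
        grp_of_pop.setdefault(p, g)
    grp_sizes = np.bincount(grp_codes)

    ssd_wg = sum(_ssd(d, np.flatnonzero(grp_codes == g)) for g in range(n_groups))
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_total - n_pops
    sigma_c = (ssd_wp / df_wp) if df_wp > 0 else 0.0

    # expected-mean-square coefficients (unbalanced design)
    sum_np2_over_ng = sum(
        pop_sizes[p] ** 2 / grp_sizes[grp_of_pop[p]] for p in range(n_pops)
    )
    sum_np2_over_n = float(np.sum(pop_sizes**2)) / n_total
    sum_ng2_over_n = float(np.sum(grp_sizes**2)) / n_total
    n1 = (n_total - sum_np2_over_ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag
    n3 = (n_total - sum_ng2_over_n) / df_ag

    if df_ap > 0:
        ms_ap = ssd_ap_wg / df_ap
        sigma_b = (ms_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    ms_ag = ssd_ag / df_ag
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _phi_from_components(
    sa: float, sb: float, sc: float, hierarchical: bool
) -> tuple[float, float | None, float | None, bool]:
    total = sa + sb + sc
    if total <= 0:
        warnings.warn("zero or negative total variance; Phi reported as 0")
        return 0.0, (0.0 if hierarchical else None), (0.0 if hierarchical else None), True
    phi_st = (sa + sb) / total
    if not hierarchical:
        return phi_st, None, None, False
    phi_ct = sa / total
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else 0.0
    return phi_st, phi_sc, phi_ct, False


def amova(
    ds: HaplotypeDataset,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    distance: np.ndarray | None = None,
) -> AmovaResult:
    """Hierarchical (or two-level) AMOVA on pairwise nucleotide differences.

    Decomposes the sum of squared pairwise differences into among-group,
    among-population-within-group and within-population variance components
    and derives Phi_ST, Phi_SC, Phi_CT.  Permutation nulls: Phi_ST permutes
    individuals among populations; Phi_SC permutes individuals among
    populations within groups; Phi_CT permutes whole populations among groups.
    p = fraction of permuted Phi >= observed.
    """
    pops = np.asarray(ds.populations)
    if len(np.unique(pops)) < 2:
        raise InputError("AMOVA needs >= 2 populations")
    hierarchical = ds.groups is not None and len(set(ds.groups)) >= 2
    groups = np.asarray(ds.groups) if hierarchical else None
    d = difference_matrix(ds.sequences) if distance is None else np.asarray(distance)

    sa, sb, sc = _variance_components(d, pops, groups)
    phi_st, phi_sc, phi_ct, degenerate = _phi_from_components(sa, sb, sc, hierarchical)
    result = AmovaResult(
        sigma_a=sa, sigma_b=sb, sigma_c=sc,
        phi_st=phi_st, phi_sc=phi_sc, phi_ct=phi_ct,
        n_permutations=n_perm, degenerate=degenerate,
    )
    if n_perm < 1 or degenerate:
        return result

    rng = np.random.default_rng(seed)
    n = len(pops)

    def phi_of(pp: np.ndarray, gg: np.ndarray | None) -> tuple[float, float | None, float | None]:
        a, b, c = _variance_components(d, pp, gg)
        return _phi_from_components(a, b, c, gg is not None)[:3]

    ge_st = ge_sc = ge_ct = 0
    for _ in range(n_perm):
        # Phi_ST null: individuals shuffled among populations (groups follow pops)
        perm = rng.permutation(n)
        st = phi_of(pops[perm], groups[perm] if hierarchical else None)[0]
        if st >= phi_st - 1e-12:
            ge_st += 1
        if hierarchical:
            # Phi_SC null: individuals shuffled within their group
            pp = pops.copy()
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                pp[idx] = pp[idx[rng.permutation(len(idx))]]
            sc_stat = phi_of(pp, groups)[1]
            if sc_stat is not None and sc_stat >= phi_sc - 1e-12:
                ge_sc += 1
            # Phi_CT null: whole populations reassigned among groups
            pop_labels = np.unique(pops)
            grp_of = {p: groups[pops == p][0] for p in pop_labels}
            shuffled = rng.permutation([grp_of[p] for p in pop_labels])
            new_grp_of = dict(zip(pop_labels, shuffled))
            gg = np.asarray([new_grp_of[p] for p in pops])
            ct_stat = phi_of(pops, gg)[2]
            if ct_stat is not None and ct_stat >= phi_ct - 1e-12:
                ge_ct += 1

    result.p_phi_st = ge_st / n_perm
    if hierarchical:
        result.p_phi_sc = ge_sc / n_perm
        result.p_phi_ct = ge_ct / n_perm
    return result


def pairwise_phist(
    ds: HaplotypeDataset, n_perm: int = DEFAULT_PERMUTATIONS, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-population AMOVA Phi_ST for every population pair.

    Returns (phi_st matrix, p-value matrix) as DataFrames indexed by
    population.  Pairs involving a single-sequence population are skipped with
    a warning (NaN).  p-values are raw (no multiple-testing correction).
    """
    pops = np.asarray(ds.populations)
    labels = list(dict.fromkeys(ds.populations))
    k = len(labels)
    if k < 2:
        raise InputError("need >= 2 populations")
    phi = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.flatnonzero((pops == labels[i]) | (pops == labels[j]))
            if min(np.sum(pops[idx] == labels[i]), np.sum(pops[idx] == labels[j])) < 2:
                warnings.warn(f"pair ({labels[i]},{labels[j]}) skipped: singleton population")
                phi.iloc[i, j] = phi.iloc[j, i] = np.nan
                continue
            sub = ds.subset(idx)
            sub.groups = None
            res = amova(sub, n_perm=n_perm, seed=int(rng.integers(2**31)))
            phi.iloc[i, j] = phi.iloc[j, i] = res.phi_st
            pval.iloc[i, j] = pval.iloc[j, i] = res.p_phi_st
    return phi, pval


# ---------------------------------------------------------------------------
# D_a, NJ tree, haplotype network
# ---------------------------------------------------------------------------


def da_distance(ds: HaplotypeDataset) -> pd.DataFrame:
    """Net nucleotide divergence between populations.

    D_a(X, Y) = D_xy - (pi_X + pi_Y)/2 with D_xy the mean between-population
    p-distance and pi the mean within-population p-distance.
    """
    pops = np.asarray(ds.populations)
    labels = list(dict.fromkeys(ds.populations))
    pd_mat = p_distance_matrix(ds.sequences)
    pi = {}
    for lab in labels:
        idx = np.flatnonzero(pops == lab)
        if len(idx) < 2:
            raise InputError(f"population '{lab}' needs >= 2 sequences")
        sub = pd_mat[np.ix_(idx, idx)]
        pi[lab] = sub[np.triu_indices(len(idx), k=1)].mean()
    out = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            ia = np.flatnonzero(pops == a)
            ib = np.flatnonzero(pops == b)
            dxy = pd_mat[np.ix_(ia, ib)].mean()
            da = dxy - (pi[a] + pi[b]) / 2
            out.iloc[i, j] = out.iloc[j, i] = da
    return out


def nj_tree(distance: pd.DataFrame, outgroup: str | None = None) -> str:
    """Neighbour-joining tree from a symmetric distance matrix, as Newick.

    Negative branch lengths are truncated to zero (logged via the underlying
    implementation's convention); when ``outgroup`` is given the tree is
    rooted on that taxon.
    """
    mat = np.asarray(distance, dtype=float)
    if not np.allclose(mat, mat.T):
        raise InputError("distance matrix must be symmetric")
    ids = [str(x) for x in distance.index]
    if len(ids) < 3:
        raise InputError("NJ needs >= 3 taxa")
    dm = DistanceMatrix(mat, ids)
    tree = nj(dm)
    if outgroup is not None:
        if outgroup not in ids:
            raise InputError(f"outgroup '{outgroup}' not in matrix")
        node = tree.find(outgroup)
        tree = tree.root_at(node.parent if node.parent is not None else node)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def population_nj_tree(ds: HaplotypeDataset, outgroup: str | None = None) -> str:
    """Population tree from D_a distances via neighbour joining."""
    return nj_tree(da_distance(ds), outgroup=outgroup)


@dataclass
class HaplotypeNetwork:
    nodes: pd.DataFrame  # haplotype, count, per-population counts
    edges: pd.DataFrame  # source, target, steps
    connection_limit: float


def haplotype_network(
    ds: HaplotypeDataset, connection_limit: float = np.inf
) -> HaplotypeNetwork:
    """Minimum-spanning network over haplotype mutational-step distances.

    Kruskal-style construction over increasing step counts: within each weight
    class every edge joining two previously distinct components is retained,
    so ties are all kept (a minimum-spanning NETWORK, not a single tree).
    Edges longer than ``connection_limit`` are removed afterwards, possibly
    disconnecting the network — a deliberately simple stand-in for a
    statistical-parsimony connection limit.
    """
    table = collapse_haplotypes(ds)
    if len(table) < 2:
        raise InputError("need >= 2 haplotypes")
    steps = difference_matrix(list(table["sequence"]))
    h = len(table)

    # per-population counts for node annotation
    pops = np.asarray(ds.populations)
    seq_to_hap = {s: hid for s, hid in zip(table["sequence"], table["haplotype"])}
    per_pop = {hid: {} for hid in table["haplotype"]}
    for seq, pop in zip(ds.sequences, pops):
        hid = seq_to_hap[seq]
        per_pop[hid][pop] = per_pop[hid].get(pop, 0) + 1
    nodes = table[["haplotype", "count", "private"]].copy()
    nodes["population_counts"] = [
        ";".join(f"{p}:{c}" for p, c in sorted(per_pop[h].items()))
        for h in nodes["haplotype"]
    ]

    parent = list(range(h))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    iu, ju = np.triu_indices(h, k=1)
    weights = steps[iu, ju]
    edges = []
    for w in np.unique(weights):
        batch = [
            (int(i), int(j))
            for i, j, ww in zip(iu, ju, weights)
            if ww == w and find(int(i)) != find(int(j))
        ]
        for i, j in batch:  # union after collecting the class, so ties survive
            edges.append((i, j, float(w)))
        for i, j in batch:
            parent[find(i)] = find(j)

    edge_df = pd.DataFrame(
        [
            {
                "source": table["haplotype"].iloc[i],
                "target": table["haplotype"].iloc[j],
                "steps": w,
            }
            for i, j, w in edges
            if w <= connection_limit
        ],
        columns=["source", "target", "steps"],
    )
    return HaplotypeNetwork(nodes=nodes, edges=edge_df, connection_limit=connection_limit)


def network_graph(net: HaplotypeNetwork):
    """The network as a networkx Graph (for layout/analysis)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in net.nodes.iterrows():
        g.add_node(row["haplotype"], count=int(row["count"]))
    for _, row in net.edges.iterrows():
        g.add_edge(row["source"], row["target"], steps=float(row["steps"]))
    return g
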