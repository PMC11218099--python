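import numpy as np
import pytest

from coldclade.genome_qc import GenomeMetadata
from coldclade.pangenome import PresenceAbsenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240702)


@pytest.fixture
def toy_matrix():
    """3 genomes; occupancies 1/3, 2/3 and 3/3."""
    return PresenceAbsenceMatrix(
        gene_ids=["g1", "g2", "g3"],
        genome_ids=["A", "B", "C"],
        occupancy=np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=bool),
    )


def make_metadata(genome_id="G", n_contigs=10, n50=100_000, completeness=99.0, contamination=0.5, **kw):
    return GenomeMetadata(
        genome_id=genome_id,
        n_contigs=n_contigs,
        n50=n50,
        completeness=completeness,
        contamination=contamination,
        **kw,
    )


def random_aai_instance(rng, n, threshold=99.5, p_link=0.3):
    """Random symmetric AAI matrix with some pairs above the threshold."""
    vals = rng.uniform(60.0, 99.0, size=(n, n))
    vals = (vals + vals.T) / 2
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_link:
                vals[i, j] = vals[j, i] = rng.uniform(threshold, 100.0)
    np.fill_diagonal(vals, 100.0)
    return vals


def bruteforce_components(adj):
    """Connected components of a boolean adjacency matrix by DFS."""
    n = adj.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(w for w in range(n) if adj[v, w] and w not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
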