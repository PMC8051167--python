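import numpy as np
import pytest

from consreg.io_formats import MsaBlock
from consreg.simulate import default_simulation_spec, simulate_ortholog_sets, write_simulation

# one fixed fixture seed for every seeded test in the suite
FIXTURE_SEED = 20210412


@pytest.fixture(scope="session")
def sim_bundle():
    """Default synthetic study: spec, toy motif library, regions, truth."""
    spec, motifs, lib_truth = default_simulation_spec(seed=FIXTURE_SEED)
    sets, truth = simulate_ortholog_sets(spec)
    return {"spec": spec, "motifs": motifs, "lib_truth": lib_truth, "sets": sets, "truth": truth}


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, sim_bundle):
    """The same synthetic study written to disk in pipeline input layout."""
    out = tmp_path_factory.mktemp("sim")
    paths = write_simulation(
        sim_bundle["sets"],
        sim_bundle["truth"],
        sim_bundle["motifs"],
        sim_bundle["lib_truth"],
        out,
    )
    paths["root"] = out
    return paths


def random_alignment(rng, n_rows=5, length=100, gap_prob=0.0, n_prob=0.0, conserved_bias=0.0):
    """A random MsaBlock; ``conserved_bias`` is the chance a column is forced identical."""
    cols = []
    for _ in range(length):
        if rng.random() < conserved_bias:
            cols.append([rng.choice(list("ACGT"))] * n_rows)
        else:
            col = []
            for _ in range(n_rows):
                r = rng.random()
                if r < gap_prob:
                    col.append("-")
                elif r < gap_prob + n_prob:
                    col.append("N")
                else:
                    col.append(rng.choice(list("ACGT")))
            cols.append(col)
    rows = {f"sp{i}": "".join(c[i] for c in cols) for i in range(n_rows)}
    # avoid all-gap rows, which would degap to empty sequences
    for sp, row in rows.items():
        if set(row) <= {"-"}:
            rows[sp] = "A" + row[1:]
    return MsaBlock(rows)


def naive_conserved_runs(msa, min_len):
    """Per-column brute-force conservation scan, independent of the PSSM path."""
    rows = list(msa.rows.values())
    conserved = []
    for i in range(msa.length):
        chars = {r[i] for r in rows}
        conserved.append(len(chars) == 1 and chars <= set("ACGT"))
    runs, start = [], None
    for i, v in enumerate(conserved):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and msa.length - start >= min_len:
        runs.append((start, msa.length))
    return runs


def naive_pwm_hits(seq, matrix, threshold, min_width, pseudocount=0.01, strands="both"):
    """Exhaustive double-loop log-odds scan returning (offset, strand, score)."""
    import math

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    w = len(matrix)
    if w < min_width:
        return []
    lo = [
        [math.log2((p + pseudocount * 0.25) / ((1 + pseudocount) * 0.25)) for p in row]
        for row in matrix
    ]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for off in range(len(seq) - w + 1):
        for strand in ("+", "-"):
            if strands != "both" and strand != strands:
                continue
            window = seq[off : off + w]
            if strand == "-":
                window = "".join(comp[b] for b in reversed(window))
            if any(b not in idx for b in window):
                continue
            score = sum(lo[i][idx[b]] for i, b in enumerate(window))
            if score >= threshold:
                hits.append((off, strand, score))
    return sorted(hits)
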