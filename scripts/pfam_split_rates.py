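#!/usr/bin/env python
"""Reproduce family split rates on a full Pfam seed multi-MSA.

Requires a local, uncompressed Pfam-A.seed file (not distributed with this
package; Pfam-A 33.1 is the release the published rates refer to).  For
each family with at least --min-seqs sequences, applies the fragment filter
and one (or --reps) runs of each requested algorithm at p=25/q=50 with
10/2 size minima, and prints the fraction of families split.

Example:
    python scripts/pfam_split_rates.py Pfam-A.seed --algorithms cluster cobalt \
        --reps 1 --seed 0

This processes 12,000+ families and can take hours for blue/cobalt at
--reps 40; use --limit for a quick partial pass.
"""

from __future__ import annotations

import argparse
import sys
from io import StringIO

import numpy as np

from famsplit.msa_io import MalformedRecordError, fragment_filter, read_stockholm_multi
from famsplit.similarity import make_graph_pair
from famsplit.splitters import ALGORITHMS, SplitConfig, split


def iter_stockholm_records(path):
    """Stream records of a large multi-MSA without loading the whole file."""
    chunk: list[str] = []
    with open(path) as fh:
        for line in fh:
            chunk.append(line)
            if line.strip() == "//":
                yield "".join(chunk)
                chunk = []


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("pfam_seed", help="Path to an uncompressed Pfam-A.seed file")
    parser.add_argument("--algorithms", nargs="+", default=["cluster", "cobalt", "blue", "indepsel"],
                        choices=sorted(ALGORITHMS))
    parser.add_argument("--min-seqs", type=int, default=12)
    parser.add_argument("--min-train", type=int, default=10)
    parser.add_argument("--min-test", type=int, default=2)
    parser.add_argument("--reps", type=int, default=1, help="run-until-n repetitions")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--limit", type=int, default=None, help="Stop after this many eligible families")
    args = parser.parse_args()

    attempted = 0
    successes = {alg: 0 for alg in args.algorithms}
    for idx, record in enumerate(iter_stockholm_records(args.pfam_seed)):
        try:
            (aln,) = read_stockholm_multi(StringIO(record))
        except MalformedRecordError as exc:
            print(f"skipping malformed record: {exc}", file=sys.stderr)
            continue
        if aln.n_rows < args.min_seqs:
            continue
        attempted += 1
        filtered = fragment_filter(aln)
        fam_seed = int(np.random.default_rng([args.seed, idx]).integers(2**31))
        cfg = SplitConfig(
            p=25, q=50, min_train=args.min_train, min_test=args.min_test,
            mode="until" if args.reps > 1 else "single",
            n_reps=args.reps, seed=fam_seed,
        )
        g_p, g_q = make_graph_pair(filtered, cfg.p, cfg.q)
        for alg in args.algorithms:
            if split(g_p, g_q, cfg, algorithm=alg).success:
                successes[alg] += 1
        if attempted % 500 == 0:
            print(f"...{attempted} families", file=sys.stderr)
        if args.limit and attempted >= args.limit:
            break

    print(f"families attempted (>= {args.min_seqs} seqs): {attempted}")
    for alg in args.algorithms:
        frac = successes[alg] / attempted if attempted else float("nan")
        print(f"{alg}\t{successes[alg]}\t{100 * frac:.1f}%")


if __name__ == "__main__":
    main()
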