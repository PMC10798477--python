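"""One-time offline build of the packaged CTM table.

Two stages, both long-running and intended for a build machine, not for
test time:

1. ``exhaustive`` -- enumerate the full 4-state binary Turing-machine
   space through the symmetry-reduced scheme in
   ``humanrand.ctm.enumerate`` (5.1e9 effective machines, ~30 min/core).
   Exact output frequencies; complete string coverage up to length 8.
2. ``sample`` -- Monte-Carlo Coding-Theorem run over the 5-state space
   (default 2.5e9 seeded uniform machines, ~1 h/core).  Unbiased
   frequency estimates in the machine class behind published
   coding-theorem tables; complete coverage through length 9 with tight
   relative error for short strings.

``assemble`` turns a counts checkpoint into the packaged TSV: direct
frequency values for the fully covered lengths, minimal-split
concatenation for the remainder up to length 12.

Usage:
    python scripts/build_ctm_table.py exhaustive --out scratch/ctm42.npz
    python scripts/build_ctm_table.py sample --out scratch/ctm52.npz
    python scripts/build_ctm_table.py assemble --counts scratch/ctm52.npz \
        --tsv src/humanrand/ctm/data/ctm_b2_d12_synthetic.tsv
"""

import argparse
import os
import sys
import time

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from humanrand.ctm import enumerate as en  # noqa: E402
from humanrand.ctm import table as tb  # noqa: E402


def run_exhaustive(args):
    n = args.n_states
    opts = en.n_options(n)
    space = opts ** (en.n_entries(n) - 1)
    counts = {0: en.counts_array(), 1: en.counts_array()}
    totals = {0: 0, 1: 0}
    branch, start = 0, 0
    ckpt = args.out + ".ckpt.npz"
    if os.path.exists(ckpt):
        d = np.load(ckpt)
        counts = {0: d["c0"], 1: d["c1"]}
        totals = {0: int(d["t0"]), 1: int(d["t1"])}
        branch, start = int(d["branch"]), int(d["start"])
        print(f"resuming at branch {branch} start {start}", flush=True)
    t0, done0 = time.time(), branch * space + start
    while branch < 2:
        stop = min(start + args.chunk, space)
        _, t = en.enumerate_reduced(n, branch, start, stop, counts[branch])
        totals[branch] += t
        start = stop
        if start >= space:
            branch, start = branch + 1, 0
        done = branch * space + start
        rate = (done - done0) / max(time.time() - t0, 1e-9)
        print(
            f"{100 * done / (2 * space):.2f}% {rate / 1e6:.2f}M mach/s "
            f"ETA {(2 * space - done) / rate / 60:.1f} min",
            flush=True,
        )
        np.savez_compressed(ckpt + ".tmp.npz", c0=counts[0], c1=counts[1],
                            t0=totals[0], t1=totals[1],
                            branch=branch, start=start)
        os.replace(ckpt + ".tmp.npz", ckpt)
    full, tot = en.assemble_full_space(n, counts[0], totals[0],
                                       counts[1], totals[1])
    sym, symtot = en.symmetrize(full, tot)
    np.savez_compressed(args.out, counts=sym, total=symtot,
                        n_states=n, method="exhaustive")
    print(f"done: {int((sym > 0).sum())} distinct strings", flush=True)


def run_sample(args):
    counts = en.counts_array()
    total = done = chunk_i = 0
    ckpt = args.out + ".ckpt.npz"
    if os.path.exists(ckpt):
        d = np.load(ckpt)
        counts, total = d["counts"], int(d["total"])
        done, chunk_i = int(d["done"]), int(d["chunk_i"])
        print(f"resuming at {done}", flush=True)
    t0, done0 = time.time(), done
    while done < args.samples:
        m = min(args.chunk, args.samples - done)
        counts, t = en.sample_space(args.n_states, m,
                                    seed=args.seed + chunk_i, counts=counts)
        total += t
        done += m
        chunk_i += 1
        rate = (done - done0) / max(time.time() - t0, 1e-9)
        print(f"{done / 1e9:.2f}G ({100 * done / args.samples:.1f}%) "
              f"{rate / 1e6:.2f}M/s", flush=True)
        np.savez_compressed(ckpt + ".tmp.npz", counts=counts, total=total,
                            done=done, chunk_i=chunk_i)
        os.replace(ckpt + ".tmp.npz", ckpt)
    sym, symtot = en.symmetrize_full_group(counts, total)
    np.savez_compressed(args.out, counts=sym, total=symtot,
                        n_states=args.n_states, method="sample",
                        n_samples=done, seed=args.seed)
    print(f"done: {int((sym > 0).sum())} distinct strings", flush=True)


def run_assemble(args):
    d = np.load(args.counts)
    ctm = en.counts_to_ctm(d["counts"], int(d["total"]))
    covered = en.covered_lengths(ctm)
    ext = en.extend_by_window_mean(ctm)
    meta = {
        "n_states": int(d["n_states"]),
        "method": str(d["method"]),
        "direct_lengths": covered,
        "extension": "window-mean at the longest covered length",
        "total_halting": int(d["total"]),
    }
    if "n_samples" in d:
        meta["n_samples"] = int(d["n_samples"])
        meta["sample_seed"] = int(d["seed"])
    label = (
        f"synthetic CTM table: {meta['method']} {meta['n_states']}-state "
        f"binary Turing-machine run, lengths {covered[0]}-{covered[-1]} "
        "direct, remainder by window-mean extension"
    )
    tb.write_table(ext, args.tsv, label, meta)
    print(f"wrote {args.tsv}: direct lengths {covered}", flush=True)


def main():
    ap = argparse.ArgumentParser()
    sub = ap.add_subparsers(dest="cmd", required=True)
    p1 = sub.add_parser("exhaustive")
    p1.add_argument("--n-states", type=int, default=4)
    p1.add_argument("--chunk", type=int, default=20_000_000)
    p1.add_argument("--out", default="scratch/ctm42.npz")
    p1.set_defaults(fn=run_exhaustive)
    p2 = sub.add_parser("sample")
    p2.add_argument("--n-states", type=int, default=5)
    p2.add_argument("--samples", type=int, default=2_500_000_000)
    p2.add_argument("--chunk", type=int, default=50_000_000)
    p2.add_argument("--seed", type=int, default=52_000)
    p2.add_argument("--out", default="scratch/ctm52.npz")
    p2.set_defaults(fn=run_sample)
    p3 = sub.add_parser("assemble")
    p3.add_argument("--counts", required=True)
    p3.add_argument("--tsv", required=True)
    p3.set_defaults(fn=run_assemble)
    args = ap.parse_args()
    args.fn(args)


if __name__ == "__main__":
    main()
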