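"""Sample core/pan accumulation curves from the pan-genomic matrix by
random genome-order permutation and fit the Heaps-style pan-growth and
exponential core-decay models."""

from __future__ import annotations

from _common import parse_args

from panmet.io import RunConfig, write_json
from panmet.panfit import fit_core_decay, fit_pan_growth, sample_curves
from panmet.pangenome import read_matrix_tsv

args = parse_args(__doc__)
config = RunConfig.from_json(args.results / "inputs" / "config.json")
out = args.results / "panfit"
out.mkdir(parents=True, exist_ok=True)

matrix = read_matrix_tsv(args.results / "pangenome" / "matrix.tsv")
curve = sample_curves(matrix, n_permutations=config.n_permutations, seed=config.seed)
curve.as_frame().to_csv(out / "curves.tsv", sep="\t", index=False)

growth = fit_pan_growth(curve)
core = fit_core_decay(curve)
write_json(
    {"pan_growth": growth.as_dict(), "core_decay": core.as_dict()},
    out / "fits.json",
)
verdict = "open" if growth.open_pangenome else "closed"
print(f"pan-genome {verdict}: ~{growth.new_families_at_N:.1f} new families per "
      f"additional genome (gamma = {growth.gamma:.2f})")
tau = f"{core.tau:.2f}" if core.tau is not None else "n/a"
print(f"core genome decays to ~{core.omega:.1f} families (tau = {tau})")
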