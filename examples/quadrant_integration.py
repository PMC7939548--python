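"""Fitness-vs-expression quadrant analysis.

Runs the full synthetic pipeline and tests whether the planted PUL is
overrepresented in the lower-right quadrant (induced protein expression,
fitness cost when disrupted) after excluding the IQR ellipse.
"""

from mfabkit.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=4, outdir="mfabkit_out/quadrant_example"))

quad = res["quadrant_tests"]
print(quad[quad["arm"] == "PFABN"].to_string(index=False))

# pul_in_quadrant counts PUL genes outside the central IQR ellipse that
# fall at x > 0 (protein induced) and y < 0 (mutant fitness cost); the
# chi-square uses all other genes with both measurements as the null.
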