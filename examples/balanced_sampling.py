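"""Balanced crop sampling: how the optimizer trades speakers against crops.

Given each speaker's number of available non-overlapping 4-s crops, the
sampler picks the crops-per-speaker value c and speakers-per-class value k
that maximize the balanced total 2*k*c.
"""

import speechdep as sd

# a toy table: class 0 speakers can supply 10/8/6 crops, class 1 speakers 9/7/3
c, k, total = sd.optimize_sampling_plan({0: [10, 8, 6], 1: [9, 7, 3]})
print(f"toy table      -> c={c} crops x k={k} speakers/class = {total} samples")

# the emulated clinical corpus: per class, 31 speakers reach 89 crops; the
# other 69 non-depressed and 11 depressed speakers are short (10 crops)
counts = {0: [89] * 31 + [10] * 69, 1: [89] * 31 + [10] * 11}
c, k, total = sd.optimize_sampling_plan(counts)
print(f"clinical-scale -> c={c} crops x k={k} speakers/class = {total} samples")
print("The optimizer keeps the 31 long speakers per class and takes 89 crops")
print("from each: the balanced training set holds 2*31*89 = 5518 samples.")
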