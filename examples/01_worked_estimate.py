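"""A worked venue-based scale-up estimate on a four-respondent toy sample.

Two key-population respondents report in-report proxies v = [2, 4] with
relative inclusion probabilities c = [1, 2]; two non-key respondents report
out-reports y = [1, 3] with c = [1, 1]; the non-key frame count is 10.
"""

import numpy as np

from vbgnsum import VenueSample, vb_gnsum

sample = VenueSample(
    person_id=np.arange(4),
    is_key=np.array([True, True, False, False]),
    c=np.array([1.0, 2.0, 1.0, 1.0]),
    y=np.array([0, 0, 1, 3], dtype=np.int64),
    v=np.array([2.0, 4.0, np.nan, np.nan]),
)

result = vb_gnsum(sample, n_frame_minus_key=10)
print(f"numerator  (est. total out-reports to K): {result.numerator_total:.4f}")
print(f"denominator (est. mean visibility of K):  {result.denominator_mean:.4f}")
print(f"estimated key population size:            {result.n_hat:.4f}")
# The numerator is 10 x mean(y) = 20 out-ties pointing at key members; each
# key member soaks up an estimated 8/3 of them, so N_K_hat = 20/(8/3) = 7.5.

inflated = result.rescale_frame(11)
print(f"with N_F\\K misstated by +10%:             {inflated.n_hat:.4f}")
# Error in the supplied frame count propagates exactly linearly: 7.5 -> 8.25.
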