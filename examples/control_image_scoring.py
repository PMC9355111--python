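"""Score a green/black/gray control image by direct pixel counting.

Control images follow the standardized convention used to benchmark
raters: green pixels are fat, black pixels are liver tissue, gray pixels
are neither.  The strict estimate is 100 * green / (green + black), so on
a rendered control phantom it must equal the stored ground truth exactly.
"""

from steatoquant import PhantomSpec, generate_control_phantom, strict_estimate_from_control

spec = PhantomSpec(target_fat_fraction=0.10, seed=7)
image, truth = generate_control_phantom(spec)
estimate = strict_estimate_from_control(image)

print(f"requested fat fraction : 10.000%")
print(f"rendered truth         : {truth.fat_fraction_percent:.4f}%")
print(f"strict pixel estimate  : {estimate:.4f}%")
print(f"exact match            : {estimate == truth.fat_fraction_percent}")
print()
print("The rendered value differs slightly from the request because disks")
print("are whole-pixel objects; the estimate matches the rendering exactly.")
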