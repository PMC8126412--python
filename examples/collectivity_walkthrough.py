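"""The collectivity index on a tiny hand-checkable configuration.

Five nuclei on one side of the organ; each is linked to its nearest
strictly-more-posterior neighbor, duplicated links count once, and the
mean link length is expressed as a percentage of the maximal organ width.
"""

from ribcage import BoundingCuboid, collectivity_index, nearest_posterior_pairs

# (x, y, z) µm; y increases toward the posterior; organ width 50 µm
nuclei = [
    (40.0, 10.0, 15.0),
    (39.0, 22.0, 15.0),
    (41.0, 31.0, 15.0),
    (38.0, 45.0, 15.0),
    (40.0, 52.0, 15.0),
]
ids = ["n1", "n2", "n3", "n4", "n5"]

for a, b, d in nearest_posterior_pairs(nuclei, ids=ids):
    print(f"link {a} -> {b}: {d:.2f} µm")

cuboid = BoundingCuboid(0, 50, 0, 100, 0, 30)
print(f"collectivity index: {collectivity_index(nuclei, cuboid, ids=ids):.2f} % of width")
# Roughly the AP spacing (about 10 µm) over the 50 µm width -> ~20%.
# Larger values mean sparser, less collective nuclear files.
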