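"""Score and select alignment paths: how peaks become assembly states.

Two conditions see peaks at {10, 30} and {11, 29}: close apexes pair up.
A third example shows a 10-fraction gap breaking into exclusive states.
"""

from secmx import enumerate_paths, path_score, select_paths

lists = [[10.0, 30.0], [11.0, 29.0]]
paths = enumerate_paths(lists, threshold=3.0)
print(f"candidate paths (2 peaks + missing per sample): {len(paths)}")
for p in sorted(paths, key=lambda p: -p.score)[:4]:
    print(f"  {p.elements}: mean={p.mean:.1f} var={p.variance:.2f} score={p.score:.3f}")

print("selected non-redundant states:")
for p in select_paths(lists, threshold=3.0):
    print(f"  {p.elements} (score {p.score:.3f})")

print("distant peaks split: apexes 10 vs 20 at threshold 3")
print(f"  joint score {path_score((10.0, 20.0), 3.0):.4f} "
      f"< solo score {path_score((10.0, None), 3.0):.4f}")
for p in select_paths([[10.0], [20.0]], threshold=3.0):
    print(f"  {p.elements}")
# Every peak ends up in exactly one state; a peak >~ threshold*sqrt(2)
# from its best partner scores better alone than matched.
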