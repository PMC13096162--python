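# Example pipeline configuration for `fibconn run-all --config ...`.
# Omitted keys keep their defaults (see fibconn.config.RunConfig).
seed: 5
n_participants: 28
duration_s: 300.0        # seconds per resting recording
fs: 128.0                # working sampling rate, Hz
conditions: [pre, post]
# Explicit ground-truth edges; delete this block to use the built-in
# default (one pre/post shared bump edge plus one post-only edge).
edges:
  pre:
    - {from_roi: left_central, to_roi: right_parietal, height: 0.25, center: 10.0, width: 1.5}
  post:
    - {from_roi: left_central, to_roi: right_parietal, height: 0.5, center: 10.0, width: 1.5}
    - {from_roi: medial_frontal, to_roi: medial_occipital, height: 0.4, center: 10.0, width: 1.5}
seg_s: 10.0
order_policy: bic
max_order: 20
k: 15
penalty: 0.02
fdr_q: 0.05
test_method: bootstrap
n_boot: 2000
include_behavior: true
out_dir: fibconn_run
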