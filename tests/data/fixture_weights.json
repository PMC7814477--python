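{"dale_signs": {"data": [1.0, 1.0, 1.0, -1.0], "shape": [4]}, "format": "cogrnn-weights", "masks": {"conn_in": {"data": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "shape": [4, 2]}, "conn_out": {"data": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "shape": [2, 4]}, "conn_rec": {"data": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "shape": [4, 4]}, "train_b_out": {"data": [1.0, 1.0], "shape": [2]}, "train_b_rec": {"data": [1.0, 1.0, 1.0, 1.0], "shape": [4]}, "train_in": {"data": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "shape": [4, 2]}, "train_out": {"data": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "shape": [2, 4]}, "train_rec": {"data": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0], "shape": [4, 4]}}, "spec": {"dales_ratio": 0.75, "dt": 10.0, "n_in": 2, "n_out": 2, "n_rec": 4, "sigma_rec": 0.05, "tau": 100.0, "transfer": "relu"}, "version": 1, "weights": {"W_in_raw": {"data": [0.5925409325868298, -1.36842743841168, 0.6193113135497005, 1.535182041596188, 0.17876240975899424, 0.484631956005955, 0.8361203696842223, -0.1226306208712346], "shape": [4, 2]}, "W_out_raw": {"data": [0.48004954320461385, -0.7823189971015903, -0.6426302414465374, 1.0829315883599557, 0.7950378660762323, -0.5157509951325804, -0.911191853746617, -0.030049021041239687], "shape": [2, 4]}, "W_rec_raw": {"data": [0.8332446336539822, -0.40126651108780914, 0.4291589147184807, -0.2496875296981901, -0.5493799660866837, 0.09327482086582303, 0.25548038639958087, 0.16949933469725884, -0.13096098652258256, 0.03191796443690463, -0.22391041600416023, -0.28156467640427457, -0.597747189464273, -0.5474446096199063, -0.16818704153586614, -0.07706554918514924], "shape": [4, 4]}, "b_out": {"data": [0.0, 0.0], "shape": [2]}, "b_rec": {"data": [0.0, 0.0, 0.0, 0.0], "shape": [4]}, "x0": {"data": [0.0, 0.0, 0.0, 0.0], "shape": [4]}}}
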