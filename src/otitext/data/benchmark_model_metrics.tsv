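model	balanced_precision	balanced_recall	accuracy	balanced_f1
simple_embedding	84.51	68.63	81.70	75.75
single_kernel_cnn	92.60	91.87	94.66	92.23
sequential_cnn	95.94	81.26	93.64	87.99
parallel_cnn	96.95	94.78	96.59	95.86
deep_parallel_cnn	96.38	93.36	96.25	94.85
ensemble	97.03	93.97	96.59	95.48
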