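ec	category
1.4.3.16	oxic
1.14.13.9	oxic
1.4.3.5	oxic
1.13.11.2	oxic
1.13.11.27	oxic
1.4.3.3	oxic
1.14.13.25	oxic
1.13.11.1	oxic
1.14.99.1	oxic
1.10.3.3	oxic
1.14.18.1	oxic
1.13.12.16	oxic
2.7.1.1	anoxic
2.7.1.11	anoxic
2.7.1.40	anoxic
2.7.2.3	anoxic
4.2.1.11	anoxic
5.3.1.1	anoxic
5.4.2.11	anoxic
1.2.1.12	anoxic
2.3.1.54	anoxic
1.2.7.1	anoxic
1.1.1.27	anoxic
2.3.1.8	anoxic
2.7.2.1	anoxic
6.2.1.1	anoxic
1.18.6.1	anoxic
1.12.7.2	anoxic
4.1.1.31	anoxic
2.7.9.2	anoxic
1.1.1.1	augmented
1.1.1.37	augmented
4.2.1.2	augmented
4.1.3.6	augmented
2.3.3.1	augmented
1.3.5.1	augmented
6.4.1.1	augmented
2.2.1.1	augmented
2.2.1.2	augmented
4.1.2.13	augmented
3.1.3.11	augmented
5.3.1.6	augmented
1.1.1.49	augmented
2.7.6.1	augmented
4.2.1.3	augmented
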