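# Default rotational-setting table: 10.17 bp phasing with minor-out at the dyad.
# minor-out band centers {0,±10,±20,±31,±41,±51,±61,±71} ±1 bp; minor-in {±5,±15,±26,±36,±46,±56,±66} ±1 bp; all else in-between.
# Editable: replace with any TSV with columns offset, category.
offset	category
-73.5	in_between
-73	in_between
-72.5	in_between
-72	minor_out
-71.5	minor_out
-71	minor_out
-70.5	minor_out
-70	minor_out
-69.5	in_between
-69	in_between
-68.5	in_between
-68	in_between
-67.5	in_between
-67	minor_in
-66.5	minor_in
-66	minor_in
-65.5	minor_in
-65	minor_in
-64.5	in_between
-64	in_between
-63.5	in_between
-63	in_between
-62.5	in_between
-62	minor_out
-61.5	minor_out
-61	minor_out
-60.5	minor_out
-60	minor_out
-59.5	in_between
-59	in_between
-58.5	in_between
-58	in_between
-57.5	in_between
-57	minor_in
-56.5	minor_in
-56	minor_in
-55.5	minor_in
-55	minor_in
-54.5	in_between
-54	in_between
-53.5	in_between
-53	in_between
-52.5	in_between
-52	minor_out
-51.5	minor_out
-51	minor_out
-50.5	minor_out
-50	minor_out
-49.5	in_between
-49	in_between
-48.5	in_between
-48	in_between
-47.5	in_between
-47	minor_in
-46.5	minor_in
-46	minor_in
-45.5	minor_in
-45	minor_in
-44.5	in_between
-44	in_between
-43.5	in_between
-43	in_between
-42.5	in_between
-42	minor_out
-41.5	minor_out
-41	minor_out
-40.5	minor_out
-40	minor_out
-39.5	in_between
-39	in_between
-38.5	in_between
-38	in_between
-37.5	in_between
-37	minor_in
-36.5	minor_in
-36	minor_in
-35.5	minor_in
-35	minor_in
-34.5	in_between
-34	in_between
-33.5	in_between
-33	in_between
-32.5	in_between
-32	minor_out
-31.5	minor_out
-31	minor_out
-30.5	minor_out
-30	minor_out
-29.5	in_between
-29	in_between
-28.5	in_between
-28	in_between
-27.5	in_between
-27	minor_in
-26.5	minor_in
-26	minor_in
-25.5	minor_in
-25	minor_in
-24.5	in_between
-24	in_between
-23.5	in_between
-23	in_between
-22.5	in_between
-22	in_between
-21.5	in_between
-21	minor_out
-20.5	minor_out
-20	minor_out
-19.5	minor_out
-19	minor_out
-18.5	in_between
-18	in_between
-17.5	in_between
-17	in_between
-16.5	in_between
-16	minor_in
-15.5	minor_in
-15	minor_in
-14.5	minor_in
-14	minor_in
-13.5	in_between
-13	in_between
-12.5	in_between
-12	in_between
-11.5	in_between
-11	minor_out
-10.5	minor_out
-10	minor_out
-9.5	minor_out
-9	minor_out
-8.5	in_between
-8	in_between
-7.5	in_between
-7	in_between
-6.5	in_between
-6	minor_in
-5.5	minor_in
-5	minor_in
-4.5	minor_in
-4	minor_in
-3.5	in_between
-3	in_between
-2.5	in_between
-2	in_between
-1.5	in_between
-1	minor_out
-0.5	minor_out
0	minor_out
0.5	minor_out
1	minor_out
1.5	in_between
2	in_between
2.5	in_between
3	in_between
3.5	in_between
4	minor_in
4.5	minor_in
5	minor_in
5.5	minor_in
6	minor_in
6.5	in_between
7	in_between
7.5	in_between
8	in_between
8.5	in_between
9	minor_out
9.5	minor_out
10	minor_out
10.5	minor_out
11	minor_out
11.5	in_between
12	in_between
12.5	in_between
13	in_between
13.5	in_between
14	minor_in
14.5	minor_in
15	minor_in
15.5	minor_in
16	minor_in
16.5	in_between
17	in_between
17.5	in_between
18	in_between
18.5	in_between
19	minor_out
19.5	minor_out
20	minor_out
20.5	minor_out
21	minor_out
21.5	in_between
22	in_between
22.5	in_between
23	in_between
23.5	in_between
24	in_between
24.5	in_between
25	minor_in
25.5	minor_in
26	minor_in
26.5	minor_in
27	minor_in
27.5	in_between
28	in_between
28.5	in_between
29	in_between
29.5	in_between
30	minor_out
30.5	minor_out
31	minor_out
31.5	minor_out
32	minor_out
32.5	in_between
33	in_between
33.5	in_between
34	in_between
34.5	in_between
35	minor_in
35.5	minor_in
36	minor_in
36.5	minor_in
37	minor_in
37.5	in_between
38	in_between
38.5	in_between
39	in_between
39.5	in_between
40	minor_out
40.5	minor_out
41	minor_out
41.5	minor_out
42	minor_out
42.5	in_between
43	in_between
43.5	in_between
44	in_between
44.5	in_between
45	minor_in
45.5	minor_in
46	minor_in
46.5	minor_in
47	minor_in
47.5	in_between
48	in_between
48.5	in_between
49	in_between
49.5	in_between
50	minor_out
50.5	minor_out
51	minor_out
51.5	minor_out
52	minor_out
52.5	in_between
53	in_between
53.5	in_between
54	in_between
54.5	in_between
55	minor_in
55.5	minor_in
56	minor_in
56.5	minor_in
57	minor_in
57.5	in_between
58	in_between
58.5	in_between
59	in_between
59.5	in_between
60	minor_out
60.5	minor_out
61	minor_out
61.5	minor_out
62	minor_out
62.5	in_between
63	in_between
63.5	in_between
64	in_between
64.5	in_between
65	minor_in
65.5	minor_in
66	minor_in
66.5	minor_in
67	minor_in
67.5	in_between
68	in_between
68.5	in_between
69	in_between
69.5	in_between
70	minor_out
70.5	minor_out
71	minor_out
71.5	minor_out
72	minor_out
72.5	in_between
73	in_between
73.5	in_between
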