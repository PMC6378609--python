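driver_id,patient_id,response,basket_roi,sequential_cohort,sequential_roi,pre_pvi_seen
1,1,termination,True,True,True,True
2,2,termination,True,True,True,True
3,3,termination,True,True,True,True
4,4,termination,True,True,True,True
5,5,termination,True,True,True,True
6,6,termination,True,True,True,True
7,7,termination,True,True,True,True
8,8,termination,True,True,True,True
9,9,termination,True,True,True,True
10,10,termination,True,True,True,True
11,11,termination,True,True,True,True
12,12,termination,True,True,True,True
13,13,termination,True,True,True,True
14,14,termination,True,True,True,True
15,15,termination,True,True,True,False
16,16,termination,True,True,True,False
17,17,termination,True,True,True,False
18,18,cl_slowing,True,True,True,True
19,19,cl_slowing,True,True,True,True
20,20,cl_slowing,True,True,True,True
21,21,cl_slowing,True,True,True,True
22,22,cl_slowing,True,True,True,True
23,23,cl_slowing,False,True,False,False
24,24,termination,True,False,False,True
25,25,termination,True,False,False,True
26,26,termination,True,False,False,False
27,27,cl_slowing,False,False,False,False
28,28,cl_slowing,False,False,False,False
29,1,cl_slowing,False,True,False,False
30,2,cl_slowing,False,True,False,False
31,3,cl_slowing,True,True,False,False
32,4,cl_slowing,True,True,False,False
33,5,cl_slowing,True,True,False,False
34,6,cl_slowing,True,True,False,False
35,7,cl_slowing,True,True,False,False
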