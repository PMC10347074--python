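# SYNTHETIC regression fixture: per-second activity counts computed by this
# package's own counts implementation on the deterministic probe signals of
# tests/conftest.py (counts_probe_signal). These are frozen self-consistency
# values guarding the numerical chain against regressions; they are not the
# output of an external reference implementation.
probe,epoch,counts_x,counts_y,counts_z
0,0,75,0,55
0,1,0,0,25
0,2,8,0,33
0,3,8,0,25
0,4,18,0,28
0,5,18,0,22
0,6,9,0,25
0,7,13,0,26
0,8,15,0,25
0,9,20,0,29
0,10,4,0,19
0,11,20,0,33
0,12,13,0,22
0,13,16,0,31
0,14,4,0,29
0,15,15,0,26
0,16,20,0,35
0,17,8,0,20
0,18,24,0,26
0,19,10,0,32
0,20,8,0,26
0,21,14,0,30
0,22,14,0,23
0,23,20,0,34
0,24,9,0,24
0,25,19,0,31
0,26,14,0,25
0,27,17,0,22
0,28,15,0,32
0,29,18,0,23
1,0,64,95,17
1,1,191,93,0
1,2,209,101,0
1,3,244,110,0
1,4,182,103,0
1,5,223,104,0
1,6,187,115,0
1,7,209,101,0
1,8,183,100,0
1,9,181,98,0
1,10,209,99,0
1,11,191,101,0
1,12,239,104,0
1,13,192,108,0
1,14,245,108,0
1,15,190,103,0
1,16,212,108,0
1,17,185,96,0
1,18,202,103,0
1,19,196,95,0
1,20,183,106,0
1,21,217,102,0
1,22,187,104,0
1,23,244,100,0
1,24,200,103,0
1,25,244,101,0
1,26,196,102,0
1,27,212,103,0
1,28,192,112,0
1,29,195,107,0
2,0,26,40,25
2,1,0,41,0
2,2,0,51,0
2,3,0,55,0
2,4,0,48,0
2,5,8,44,0
2,6,0,59,0
2,7,0,44,0
2,8,0,53,0
2,9,0,66,0
2,10,0,48,0
2,11,9,48,0
2,12,4,61,0
2,13,4,51,0
2,14,4,50,0
2,15,0,57,0
2,16,0,48,0
2,17,0,49,0
2,18,4,54,0
2,19,14,55,0
2,20,0,47,0
2,21,0,60,0
2,22,4,48,0
2,23,8,48,0
2,24,12,55,0
2,25,0,52,0
2,26,13,44,0
2,27,4,58,0
2,28,4,62,0
2,29,8,45,0
3,0,35,101,11
3,1,75,104,0
3,2,44,85,0
3,3,79,84,0
3,4,80,100,0
3,5,35,89,0
3,6,80,82,0
3,7,76,97,0
3,8,37,86,0
3,9,74,82,0
3,10,71,99,0
3,11,35,96,0
3,12,73,74,4
3,13,71,94,0
3,14,33,102,4
3,15,72,89,0
3,16,78,80,4
3,17,32,92,0
3,18,66,101,0
3,19,70,91,0
3,20,31,78,0
3,21,87,91,0
3,22,72,95,4
3,23,33,89,0
3,24,72,87,0
3,25,73,95,0
3,26,35,95,0
3,27,68,93,0
3,28,69,94,0
3,29,30,90,4
4,0,22,99,62
4,1,24,45,47
4,2,26,8,43
4,3,32,0,56
4,4,18,0,47
4,5,17,0,48
4,6,24,0,53
4,7,26,0,39
4,8,29,0,47
4,9,21,0,49
4,10,28,0,44
4,11,20,0,55
4,12,20,0,45
4,13,29,0,42
4,14,25,0,56
4,15,18,0,41
4,16,23,0,42
4,17,23,0,55
4,18,31,0,46
4,19,25,0,45
4,20,17,0,54
4,21,24,0,50
4,22,22,0,53
4,23,30,0,47
4,24,25,0,44
4,25,25,0,55
4,26,22,0,48
4,27,26,0,41
4,28,27,0,61
4,29,30,0,45
5,0,65,79,32
5,1,9,24,0
5,2,13,14,0
5,3,16,0,0
5,4,24,0,0
5,5,20,4,0
5,6,23,0,0
5,7,27,0,0
5,8,17,0,0
5,9,24,0,0
5,10,24,0,0
5,11,22,0,0
5,12,23,0,0
5,13,16,0,0
5,14,17,0,0
5,15,27,0,0
5,16,24,0,0
5,17,31,0,0
5,18,19,0,0
5,19,13,0,0
5,20,23,0,0
5,21,20,0,0
5,22,25,4,0
5,23,19,4,0
5,24,20,4,0
5,25,28,0,0
5,26,17,0,0
5,27,19,0,0
5,28,29,0,0
5,29,18,0,0
6,0,68,0,0
6,1,66,0,0
6,2,60,0,0
6,3,61,0,0
6,4,58,0,0
6,5,79,0,0
6,6,56,0,0
6,7,60,0,0
6,8,77,0,0
6,9,56,0,0
6,10,63,0,0
6,11,66,0,0
6,12,62,0,0
6,13,62,0,0
6,14,65,0,0
6,15,66,0,0
6,16,68,0,0
6,17,61,0,0
6,18,58,0,0
6,19,72,0,0
6,20,61,0,0
6,21,65,0,0
6,22,60,0,0
6,23,57,0,0
6,24,64,0,0
6,25,66,0,0
6,26,64,0,0
6,27,64,0,0
6,28,57,0,0
6,29,58,0,0
7,0,33,181,49
7,1,18,254,4
7,2,26,227,0
7,3,27,193,0
7,4,31,236,0
7,5,17,230,0
7,6,26,206,0
7,7,20,215,0
7,8,23,243,0
7,9,26,201,0
7,10,25,210,0
7,11,21,241,0
7,12,25,217,0
7,13,23,207,0
7,14,19,233,0
7,15,32,236,0
7,16,24,202,0
7,17,23,206,0
7,18,27,240,0
7,19,21,206,0
7,20,24,199,0
7,21,31,233,0
7,22,31,239,0
7,23,23,199,0
7,24,28,221,0
7,25,27,257,0
7,26,25,206,0
7,27,27,197,0
7,28,30,238,0
7,29,28,238,0
8,0,83,190,17
8,1,64,202,31
8,2,80,202,16
8,3,78,191,20
8,4,91,196,25
8,5,67,199,26
8,6,81,196,22
8,7,75,196,24
8,8,86,201,24
8,9,70,196,10
8,10,76,202,14
8,11,68,206,27
8,12,93,200,20
8,13,74,184,17
8,14,81,190,13
8,15,72,199,19
8,16,91,197,21
8,17,73,199,32
8,18,86,197,21
8,19,73,199,22
8,20,89,201,24
8,21,73,205,18
8,22,74,191,8
8,23,68,183,20
8,24,79,185,14
8,25,81,202,12
8,26,65,200,18
8,27,76,209,21
8,28,75,201,27
8,29,87,202,20
9,0,58,185,61
9,1,83,181,18
9,2,86,200,11
9,3,78,212,4
9,4,75,209,4
9,5,72,210,0
9,6,69,199,4
9,7,74,194,0
9,8,72,202,4
9,9,77,212,0
9,10,84,216,0
9,11,85,212,0
9,12,69,183,0
9,13,80,215,5
9,14,86,221,4
9,15,88,213,0
9,16,78,203,0
9,17,74,194,8
9,18,65,202,0
9,19,58,208,5
9,20,84,206,8
9,21,84,206,0
9,22,91,204,4
9,23,77,186,0
9,24,68,214,0
9,25,70,215,0
9,26,84,216,0
9,27,80,203,4
9,28,80,186,0
9,29,73,203,8
10,0,0,120,0
10,1,0,138,0
10,2,0,139,0
10,3,0,138,0
10,4,0,139,0
10,5,0,139,0
10,6,0,139,0
10,7,0,139,0
10,8,0,139,0
10,9,0,139,0
10,10,0,139,0
10,11,0,139,0
10,12,0,139,0
10,13,0,139,0
10,14,0,139,0
10,15,0,139,0
10,16,0,139,0
10,17,0,139,0
10,18,0,139,0
10,19,0,139,0
10,20,0,139,0
10,21,0,139,0
10,22,0,139,0
10,23,0,139,0
10,24,0,139,0
10,25,0,139,0
10,26,0,139,0
10,27,0,139,0
10,28,0,139,0
10,29,0,139,0
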