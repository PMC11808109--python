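# Segment file format

A segment file is a concatenation of constant-length segments, one per
cell frame. All integers are little-endian.

## Header (32 bytes)

| offset | size | field            | notes                              |
|-------:|-----:|------------------|------------------------------------|
| 0      | 4    | magic            | ASCII `OTS1`, checked per segment  |
| 4      | 4    | frame_index u32  | read order is restored by this key |
| 8      | 8    | start_pulse u64  | global pulse index of the ROI row 0|
| 16     | 2    | skip u16         | line decimation factor (≥ 1)       |
| 18     | 2    | n_seg u16        | image rows per segment             |
| 20     | 2    | window_px u16    | pixels per row (64 by default)     |
| 22     | 2    | flags u16        | bit 0 padded, bit 1 split, bit 2 large_window; upper bits reserved |
| 24     | 2    | size_um_x100 u16 | equivalent circular diameter ×100  |
| 26     | 2    | granularity_x100 u16 | `G = k(N_x+N_y)` ×100          |
| 28     | 4    | opacity u32      | total masked 8-bit intensity       |

## Payload

`n_seg × window_px` bytes of 8-bit absorbance-positive image data, row
major (rows = decimated pulses in flow order). Total segment length is
therefore `32 + n_seg × window_px`, constant within a file; a file whose
length is not a multiple of it, or whose magic does not appear at a
segment boundary, is rejected with the offending byte offset.
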