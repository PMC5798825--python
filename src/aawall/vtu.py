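"""Minimal ASCII VTU (VTK XML unstructured grid) writer for tet meshes."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtu"]


def _data_array(fh, name, data, n_comp):
    fh.write(f'    <DataArray type="Float64" Name="{name}" '
             f'NumberOfComponents="{n_comp}" format="ascii">\n')
    flat = np.asarray(data, dtype=float).reshape(-1, n_comp)
    for row in flat:
        fh.write("     " + " ".join(f"{v:.9g}" for v in row) + "\n")
    fh.write("    </DataArray>\n")


def write_vtu(path, nodes, tets, point_data=None, cell_data=None):
    """Write a tetrahedral mesh with optional point/cell arrays as ASCII VTU."""
    nodes = np.asarray(nodes)
    tets = np.asarray(tets)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write(' <UnstructuredGrid>\n')
        fh.write(f'  <Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{len(tets)}">\n')
        fh.write('   <Points>\n')
        _data_array(fh, "Points", nodes, 3)
        fh.write('   </Points>\n')
        fh.write('   <Cells>\n')
        fh.write('    <DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for row in tets:
            fh.write("     " + " ".join(str(int(v)) for v in row) + "\n")
        fh.write('    </DataArray>\n')
        fh.write('    <DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write("     " + " ".join(str(4 * (i + 1)) for i in range(len(tets))) + "\n")
        fh.write('    </DataArray>\n')
        fh.write('    <DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write("     " + " ".join("10" for _ in range(len(tets))) + "\n")
        fh.write('    </DataArray>\n')
        fh.write('   </Cells>\n')
        if point_data:
            fh.write('   <PointData>\n')
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                nc = 1 if arr.ndim == 1 else arr.shape[-1]
                _data_array(fh, name, arr, nc)
            fh.write('   </PointData>\n')
        if cell_data:
            fh.write('   <CellData>\n')
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                nc = 1 if arr.ndim == 1 else int(np.prod(arr.shape[1:]))
                _data_array(fh, name, arr, nc)
            fh.write('   </CellData>\n')
        fh.write('  </Piece>\n </UnstructuredGrid>\n</VTKFile>\n')
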